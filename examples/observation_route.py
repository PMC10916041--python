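"""Build a school observation route by nearest-neighbor sampling.

On a 3x3-block street grid with the school mid-block, the route contains
the single access segment fronting the entrance, its two 4-way endpoint
intersections as crossings (plus any school driveways on the access
segment), and the six non-access streets incident to those crossings,
each audited on one side.
"""

from maps_srts import count_route_units, generate_grid_network, select_route

network = generate_grid_network(3, 3, school_block=(1, 1), driveways=2)
route = select_route(network)
n_access, n_crossings, n_other = count_route_units(route)

print(f"access segments : {n_access}  -> {route.access_segments}")
print(f"crossings       : {n_crossings}  -> {route.crossings}")
print(f"other segments  : {n_other}  -> {route.other_segments}")
print("\nEvery other segment touches a crossing of the access segment "
      "(one-hop rule); the two 'drv' crossings are school driveways, which "
      "count as crossings but do not split the access segment.")
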