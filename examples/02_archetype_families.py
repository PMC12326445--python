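"""RSV/hRSV across synthetic network archetypes.

Generates the archetype families at matched size and density and prints
both measures: core-periphery structure drives RSV up, while only the
heterogeneous geometric family (diverse connectivity patterns among
similar-strength nodes) pushes the small-window hRSV up.
"""

from rsvnet import GeneratorSpec, generate, hrsv, rsv

families = ["er", "geometric", "hetero_geometric", "star_like", "lattice"]
print(f"{'family':<18} {'RSV':>8} {'hRSV(w=4)':>10}")
for family in families:
    vals_rsv, vals_h = [], []
    for seed in range(10):
        net = generate(GeneratorSpec(family=family, n=85, density=0.6, seed=seed))
        vals_rsv.append(rsv(net).value)
        vals_h.append(hrsv(net, 4).value)
    mean = lambda xs: sum(xs) / len(xs)
    print(f"{family:<18} {mean(vals_rsv):>8.4f} {mean(vals_h):>10.4f}")

# Expected pattern: the hub-heavy families (star_like, hetero_geometric)
# dominate RSV; hetero_geometric tops the small-window hRSV; the lattice
# is lowest on both; ER is low on hRSV because random graphs, like
# regular ones, lack statistical complexity.
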