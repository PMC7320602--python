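"""Inspect the search schemes that drive approximate matching.

Prints, for each supported mismatch count, the searches of the shipped
scheme and the error distributions each search covers.  The searches of
a scheme partition all per-piece error distributions, which is why
occurrence counts found by different searches can simply be summed.
"""

from mappability.search_schemes import (
    all_distributions,
    covered_distributions,
    scheme_for,
)

for e in range(3):
    scheme = scheme_for(e)
    total = all_distributions(scheme.p, e)
    print(f"\ne={e}: {len(scheme.searches)} search(es), "
          f"{scheme.p} piece(s), {len(total)} error distributions")
    for s in scheme.searches:
        covered = sorted(covered_distributions(s, e))
        rendered = " ".join("".join(map(str, t)) for t in covered)
        print(f"  pi={s.pi} L={s.lower} U={s.upper}  covers: {rendered}")
# For e=2 the three searches are the published optimum scheme: the
# forward search covers 3 distributions, the backward search 5, and the
# bidirectional search (starting at the third piece) the remaining 7.
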