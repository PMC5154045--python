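"""Screen a primer pair against SSR marker-design criteria.

The default criteria are the usual marker-development windows: primer
length 18-22 bp, Tm 50-60 degC, GC 40-60%, product 100-300 bp.  The
report lists every measured value with its verdict.
"""

from ssrchar import PrimerPair, screen_primer_pair

pair = PrimerPair(
    forward="GTGCAACACTATGACACCAG",
    reverse="ACAGTGCCCAATTGTTGT",
    product_size=177,
)

for method in ("wallace", "nearest_neighbor"):
    report = screen_primer_pair(pair, tm_method=method)
    print(f"Tm method: {method}  ->  overall pass: {report.passed}")
    for check in report.checks:
        verdict = "ok" if check.passed else "FAIL"
        print(f"  {check.criterion:<15} {check.value:7.2f}  "
              f"[{check.low}, {check.high}]  {verdict}")
# The Wallace rule (2(A+T)+4(G+C)) and the thermodynamic nearest-neighbor
# model give different Tm estimates; a pair near a window edge can pass
# under one method and fail under the other.
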