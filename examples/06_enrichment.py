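"""Hypergeometric term enrichment of miRNA target genes.

The synthetic annotation concentrates one term on miRNA target transcripts;
enrichment of the target set against the full annotation should rank it
first.
"""

from srnapipe.config import RunConfig, SimulationConfig
from srnapipe.pipeline import run_enrichment_demo

results = run_enrichment_demo(SimulationConfig(seed=4), RunConfig(seed=4))

print(f"{'term':24s} {'TB':>4s} {'TS':>4s} {'B':>4s} {'S':>4s} "
      f"{'p':>10s} significant")
for r in results:
    i = r.input
    print(f"{r.term:24s} {i.TB:4d} {i.TS:4d} {i.B:4d} {i.S:4d} "
          f"{r.p:10.3g} {r.significant}")
# p = P(X >= S) for X ~ Hypergeom(TB, B, TS): the chance that S or more of
# the TS selected genes would carry the term if selection were random.
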