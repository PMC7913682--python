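"""Recover a planted conserved pentamer by positional enrichment and ranking.

Plants a conserved GCUGC motif (a splicing-factor binding core; DNA
GCTGC) in the downstream introns of 'decreased inclusion' foreground
exons at a 60% rate versus 10% in background exons, then runs the 50-nt
sliding-window Fisher/BH enrichment scan and the per-pentamer ΔPSI
linear-model ranking.
"""

import numpy as np

from splicedex.motif import dna_to_rna, rank_pentamers, window_enrichment
from splicedex.simulate import PlantedMotif, simulate_flanks

rng = np.random.default_rng(34)
planted = [PlantedMotif("GCTGC", "downstream_intron", window=(20, 150),
                        fg_rate=0.6, bg_rate=0.1)]
fg, bg, truth = simulate_flanks(
    100, 100, rng, planted=planted, slopes={"GCTGC": -0.1},
    foreground_label="foreground_down",
)
print(f"simulated {len(fg)} foreground / {len(bg)} background exons; "
      f"{len(truth[truth.set != 'background'])} planted foreground occurrences")

enrich = window_enrichment(fg, bg, window=50)
top = enrich.sort_values(["q", "p"]).iloc[0]
print(
    f"\ntop enriched window: {dna_to_rna(top.pentamer)} in {top.region} "
    f"at offset {top.window_start} "
    f"(fold = {top.fold_enrichment:.1f}, q = {top.q:.2e})"
)

ranks = rank_pentamers(fg)
print("\npentamers ranked by adjusted R^2 of the ΔPSI linear model:")
for row in ranks.head(3).itertuples():
    print(f"  {row.rank}. {dna_to_rna(row.pentamer)}  adj R^2 = {row.adj_r2:.3f}")
# The planted motif is the most significant positional hit in the correct
# region and the best linear predictor of ΔPSI.
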