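"""Quantify percent spliced in (PSI) from simulated amplicon reads.

Simulates error-free reads for one cassette-exon event at a known
inclusion fraction, classifies each read by the splice junction it spans,
and reports PSI with its exact binomial confidence interval -- once with
unbiased amplification and once with PCR length bias, to show the
under-detection of the longer (inclusion) amplicon.
"""

import numpy as np

from splicedex.quantify import align_reads_exact, classify_reads, count_and_psi
from splicedex.simulate import DEFAULT_LENGTH_BIAS, simulate_reads, synthetic_panel

panel = synthetic_panel()
ref = panel.refs["Ttn"]  # 303 nt cassette: the panel's largest
true_psi = 0.5

for lam, label in ((0.0, "unbiased"), (DEFAULT_LENGTH_BIAS, "length-biased")):
    rng = np.random.default_rng(0)
    reads, truth = simulate_reads(ref, true_psi, 20000, rng, lam=lam)
    alignments = align_reads_exact([(r.read_id, r.sequence) for r in reads], ref)
    classified = classify_reads(alignments, ref, min_overhang=8)
    counts, psi = count_and_psi(classified, min_reads=20, event_id="Ttn")
    print(
        f"{label:>13}: PSI = {psi.psi:.3f} "
        f"[{psi.ci_low:.3f}, {psi.ci_high:.3f}] from "
        f"{counts.n_informative} informative reads "
        f"(expected pool fraction {truth['observed_p_inclusion']:.3f})"
    )
# The biased run under-detects inclusion by several PSI points because
# the exclusion amplicon, shorter by the cassette length, amplifies with
# higher per-cycle efficiency.
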