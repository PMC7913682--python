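"""Synthetic data generators for every stage of the targeted splice assay.

Three generators emulate the statistical structure the pipeline assumes:

* :func:`simulate_reads` — error-free amplicon reads for one splice event,
  with isoform choice binomial in the true inclusion fraction, optionally
  distorted by length-dependent PCR amplification bias.  Per-cycle
  efficiency decays exponentially with amplicon length,
  ``e(L) = e_max * exp(-lambda * L)``, so after ``cycles`` rounds an
  isoform of length L carries weight ``(1 + e(L)) ** cycles``; the longer
  (inclusion) amplicon is then under-represented, reproducing the
  detection bias of targeted assays and its growth with cassette size.

* :func:`simulate_cohort` — a genotype ladder: each group has a latent
  splicing-factor-loss activity x in [0, 1.2] that drives every event's
  mean PSI through its four-parameter logistic truth curve; realized PSI
  adds beta-distributed noise and binomial read sampling.

* :func:`simulate_flanks` — exon flanking sequences with conservation
  tracks, optionally planting conserved pentamer motifs at given rates in
  positional windows, and ΔPSI values linear in the planted-motif counts.

A bundled synthetic 36-event panel (:func:`synthetic_panel`) mirrors the
published assay design for myotonic dystrophy mouse models: 23 events
chosen for large PSI shifts, 12 patient-validated events, and one
negative-control event in Brd2; cassette sizes for the well-characterized
events (e.g. Ryr1 15 nt, Bin1 45 nt, Clcn1 79 nt, Ttn 303 nt) match their
described exons, while all sequences, primers and remaining sizes are
synthetic.  Every generator is deterministic given its random generator /
seed, and every dataset is returned alongside a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import REGION_LENGTHS, REGIONS, ExonFlankRecord, _flank_counts, pentamer_code
from .panel import AmpliconDesign, SpliceEvent
from .quantify import IsoformReference, build_isoform_refs

__all__ = [
    "SimRead",
    "PlantedMotif",
    "CohortSim",
    "SyntheticPanel",
    "simulate_reads",
    "observed_inclusion_probability",
    "simulate_cohort",
    "simulate_flanks",
    "synthetic_panel",
    "default_event_curves",
    "mdx_psi_table",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))

#: Default per-cycle length-bias coefficient (1/nt).  Calibrated so that a
#: ~600 bp amplicon panel shows per-event under-detection of inclusion on
#: the scale targeted assays exhibit in practice: roughly -2 points for a
#: 45 nt cassette up to about -10 points for a 300 nt cassette at 15
#: cycles, a few points on average.  Pass ``lam=0`` for unbiased
#: amplification.
DEFAULT_LENGTH_BIAS = 2e-4


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# Read-level simulation

@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    true_isoform: str  # "inclusion" or "exclusion"


def observed_inclusion_probability(
    true_psi: float,
    len_inclusion: int,
    len_exclusion: int,
    lam: float = 0.0,
    e_max: float = 0.9,
    cycles: int = 15,
) -> float:
    """Expected inclusion fraction in the amplicon pool under length bias.

    With per-cycle efficiency ``e(L) = e_max * exp(-lam * L)`` the isoform
    weights after PCR are ``w = (1 + e(L)) ** cycles`` and the observed
    inclusion probability is ``psi * w_inc / (psi * w_inc + (1 - psi) *
    w_exc)``.  ``lam = 0`` gives unbiased amplification (returns
    ``true_psi``).
    """
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError("true_psi must be in [0, 1]")
    if lam < 0:
        raise ValueError("length-bias coefficient lambda must be >= 0")
    w_inc = (1.0 + e_max * np.exp(-lam * len_inclusion)) ** cycles
    w_exc = (1.0 + e_max * np.exp(-lam * len_exclusion)) ** cycles
    num = true_psi * w_inc
    den = num + (1.0 - true_psi) * w_exc
    return float(num / den)


def _junction_spanning_starts(
    length: int, junctions: tuple[int, ...], read_len: int, overhang: int
) -> np.ndarray:
    """Start positions whose read spans >= 1 junction with the overhang."""
    valid: list[np.ndarray] = []
    for j in junctions:
        lo = max(0, j + overhang - read_len)
        hi = min(length - read_len, j - overhang)
        if hi >= lo:
            valid.append(np.arange(lo, hi + 1))
    if not valid:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(valid))


def simulate_reads(
    ref: IsoformReference,
    true_psi: float,
    n_reads: int,
    rng: np.random.Generator,
    read_len: int = 150,
    lam: float = 0.0,
    e_max: float = 0.9,
    cycles: int = 15,
    junction_overhang: int = 8,
) -> tuple[list[SimRead], dict]:
    """Draw error-free single-end reads from one event's amplicon pool.

    Each fragment picks an isoform with the (possibly bias-distorted)
    inclusion probability, then a start position uniform over the starts
    whose read spans a splice junction of that isoform with at least
    ``junction_overhang`` nt on each side (for the inclusion isoform this
    weights the two junctions exactly as uniform fragmentation would).
    Conditioning on junction coverage keeps the informative-read tally
    binomial in the pool inclusion fraction, so the estimator is unbiased
    when amplification is unbiased (``lam = 0``).  Returns the reads and a
    truth entry recording the generating parameters and isoform tally.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    lens = {"inclusion": len(ref.inclusion_seq), "exclusion": len(ref.exclusion_seq)}
    if read_len > min(lens.values()):
        raise ValueError(
            f"read_len ({read_len}) exceeds the exclusion amplicon "
            f"({lens['exclusion']} nt) for {ref.event.event_id}"
        )
    starts = {
        iso: _junction_spanning_starts(
            lens[iso], ref.junctions(iso), read_len, junction_overhang
        )
        for iso in ("inclusion", "exclusion")
    }
    for iso, s in starts.items():
        if len(s) == 0:
            raise ValueError(
                f"{ref.event.event_id}: no junction-spanning start positions "
                f"for the {iso} isoform at read_len={read_len}"
            )
    p_inc = observed_inclusion_probability(
        true_psi, lens["inclusion"], lens["exclusion"], lam, e_max, cycles
    )
    is_inc = rng.random(n_reads) < p_inc
    reads: list[SimRead] = []
    for i, inc in enumerate(is_inc):
        iso = "inclusion" if inc else "exclusion"
        seq = ref.sequence(iso)
        start = int(rng.choice(starts[iso]))
        reads.append(
            SimRead(
                read_id=f"{ref.event.event_id}:{i}",
                sequence=seq[start : start + read_len],
                true_isoform=iso,
            )
        )
    truth = dict(
        event_id=ref.event.event_id,
        true_psi=true_psi,
        observed_p_inclusion=p_inc,
        n_reads=n_reads,
        n_inclusion_true=int(is_inc.sum()),
        lam=lam,
        e_max=e_max,
        cycles=cycles,
    )
    return reads, truth


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    """Write simulated reads as FASTQ (uniform high base quality)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Synthetic panel

# Cassette-exon sizes (nt).  The first ten are the sizes described for the
# corresponding exons; the rest are synthetic draws fixed once so that the
# panel reproduces the assay's design statistics (cassette ~14 +/- 11 % of
# amplicon length; amplicons ~617 +/- 87 bp).
_CASSETTE_LEN = {
    "Ryr1": 15, "Dctn4": 21, "Bin1": 45, "Clcn1": 79, "Brd2": 92, "Mbnl2": 95,
    "Map3k4": 156, "Fn1": 270, "Trim55": 288, "Ttn": 303,
    "Atp2a1": 46, "Best3": 40, "Clasp1": 109, "Kif13a": 40, "Mbnl1": 149,
    "Nfix": 34, "Opa1": 78, "Vps39": 91, "Abcc9": 87, "Cpeb2": 52,
    "Eya4": 54, "Neb": 52, "Phka1": 132, "Ldb3": 98, "Lrrfip2": 56,
    "Cacna2d1": 35, "Jag2": 26, "Ppp3cc": 40, "Mpdz": 59, "Ank2": 24,
    "Camk2b": 74, "Gfpt1": 89, "Pdlim3": 61, "Sorbs1": 100, "Tnnt3": 54,
    "Arfgap2": 59,
}

_INCLUSION_LEN = {
    "Ryr1": 587, "Dctn4": 744, "Bin1": 524, "Clcn1": 820, "Brd2": 618,
    "Mbnl2": 628, "Map3k4": 563, "Fn1": 572, "Trim55": 687, "Ttn": 786,
    "Atp2a1": 480, "Best3": 552, "Clasp1": 695, "Kif13a": 665, "Mbnl1": 635,
    "Nfix": 543, "Opa1": 634, "Vps39": 598, "Abcc9": 781, "Cpeb2": 644,
    "Eya4": 584, "Neb": 647, "Phka1": 630, "Ldb3": 676, "Lrrfip2": 629,
    "Cacna2d1": 530, "Jag2": 444, "Ppp3cc": 716, "Mpdz": 609, "Ank2": 573,
    "Camk2b": 568, "Gfpt1": 483, "Pdlim3": 629, "Sorbs1": 663, "Tnnt3": 673,
    "Arfgap2": 487,
}

#: 12 events also validated in patient muscle; the remaining test events
#: were selected for large PSI shifts in the disease models.
PATIENT_VALIDATED = (
    "Atp2a1", "Best3", "Bin1", "Clasp1", "Clcn1", "Kif13a",
    "Mbnl1", "Mbnl2", "Nfix", "Opa1", "Ryr1", "Vps39",
)

NEGATIVE_CONTROL = "Brd2"

_PANEL_SEED = 20210127  # fixed: the panel is a frozen synthetic artifact


@dataclass(frozen=True)
class SyntheticPanel:
    """A frozen synthetic splice panel: designs plus isoform references."""

    designs: tuple[AmpliconDesign, ...]
    refs: Mapping[str, IsoformReference]

    @property
    def events(self) -> list[SpliceEvent]:
        return [d.event for d in self.designs]

    @property
    def roles(self) -> dict[str, str]:
        return {e.event_id: e.role for e in self.events}


def synthetic_panel() -> SyntheticPanel:
    """Build the bundled synthetic 36-event panel (deterministic).

    Composition: 23 large-shift events + 12 patient-validated events
    (35 test events) + 1 negative control (Brd2).  Sequences and primers
    are synthetic; sizes follow the module docstring.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    genes = list(_CASSETTE_LEN)
    designs: list[AmpliconDesign] = []
    refs: dict[str, IsoformReference] = {}
    pools = ["A", "B", "C", "D"] * 9
    for i, gene in enumerate(genes):
        c_len = _CASSETTE_LEN[gene]
        inc_len = _INCLUSION_LEN[gene]
        exc_len = inc_len - c_len
        # split the non-cassette length into flanks; keep one primer close
        # (<125 nt) to the cassette exon
        up_len = 60 + int(rng.integers(0, 60))
        down_len = exc_len - up_len
        event = SpliceEvent(
            event_id=gene,
            gene=gene,
            cassette_len=c_len,
            chrom=f"chr{1 + i % 19}",
            start=1_000_000 + 10_000 * i,
            end=1_000_000 + 10_000 * i + c_len,
            strand="+" if i % 2 == 0 else "-",
            role="negative_control" if gene == NEGATIVE_CONTROL else "test",
        )
        up = _random_seq(rng, up_len)
        cassette = _random_seq(rng, c_len)
        down = _random_seq(rng, down_len)
        refs[gene] = build_isoform_refs(event, up, cassette, down)
        designs.append(
            AmpliconDesign(
                event=event,
                fwd_primer=up[:20],
                rev_primer=_revcomp(down[-20:]),
                fwd_distance=up_len - 20,
                rev_distance=down_len - 20,
                inclusion_len=inc_len,
                exclusion_len=exc_len,
                pool=pools[i],
                primer_conc=200 if i % 5 else 50,
            )
        )
    return SyntheticPanel(designs=tuple(designs), refs=refs)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Cohort simulation

def _four_pl(x: float, init: float, final: float, ec50: float, hill: float) -> float:
    if x <= 0:
        return init
    xh = x**hill
    return init + (final - init) * xh / (xh + ec50**hill)


def default_event_curves(
    events: Sequence[SpliceEvent],
    rng: np.random.Generator,
) -> dict[str, tuple[float, float, float, float]]:
    """Draw plausible truth 4PL curves (init, final, ec50, hill) per event.

    Test events shift by 0.3-0.5 PSI in an alternating direction with EC50
    in [0.2, 0.6]; the Hill coefficient is drawn so that the curve reaches
    >= 90% of its shift at severity x = 1 (panel events revert essentially
    fully to the fetal pattern in the most severe disease models, which is
    what anchors the index at 1).  The negative control is flat.
    """
    curves: dict[str, tuple[float, float, float, float]] = {}
    for i, event in enumerate(events):
        if event.role == "negative_control":
            init = float(rng.uniform(0.3, 0.7))
            curves[event.event_id] = (init, init, 0.5, 1.0)
            continue
        shift = float(rng.uniform(0.3, 0.5))
        if i % 2 == 0:
            init = float(rng.uniform(0.55, 0.9))
            final = init - shift
        else:
            init = float(rng.uniform(0.1, 0.45))
            final = init + shift
        ec50 = float(rng.uniform(0.2, 0.6))
        # >=90% of the shift at x=1 requires ec50**hill <= 1/9
        hill_min = np.log(1 / 9) / np.log(ec50)
        hill = float(rng.uniform(hill_min, hill_min + 2.5))
        curves[event.event_id] = (init, final, ec50, hill)
    return curves


@dataclass(frozen=True)
class CohortSim:
    psi: pd.DataFrame       # event x sample realized PSI (from counts)
    counts: pd.DataFrame    # long: sample, event, n_inclusion, n_exclusion
    samples: pd.DataFrame   # sample_id, group, tissue, latent_activity
    truth: pd.DataFrame     # sample x event true PSI + generating curves


def simulate_cohort(
    events: Sequence[SpliceEvent],
    curves: Mapping[str, tuple[float, float, float, float]],
    groups: Sequence[tuple[str, int, float]],
    rng: np.random.Generator,
    noise_sd: float = 0.03,
    n_reads: int = 1000,
    tissue: str = "quadriceps",
) -> CohortSim:
    """Simulate a cohort across a latent activity ladder.

    ``groups`` is a list of (group label, n_samples, latent activity x);
    each event's mean PSI at x comes from its truth 4PL curve, realized
    PSI adds beta noise with standard deviation ``noise_sd`` (0 for the
    degenerate noiseless limit), and the reported PSI is a binomial draw
    of ``n_reads`` informative reads.
    """
    if len({x for _, _, x in groups}) < 1:
        raise ValueError("at least one group required")
    for _, n, x in groups:
        if n <= 0:
            raise ValueError("group sizes must be > 0")
        if x < 0:
            raise ValueError("latent activities must be >= 0")
    sample_rows = []
    for group, n, x in groups:
        for k in range(n):
            sample_rows.append((f"{group}_{k+1:02d}", group, tissue, x))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "tissue", "latent_activity"]
    )

    event_ids = [e.event_id for e in events]
    psi = pd.DataFrame(index=event_ids, columns=samples["sample_id"], dtype=float)
    truth_rows = []
    count_rows = []
    for eid in event_ids:
        init, final, ec50, hill = curves[eid]
        for sid, x in zip(samples["sample_id"], samples["latent_activity"]):
            mean = float(np.clip(_four_pl(float(x), init, final, ec50, hill), 1e-4, 1 - 1e-4))
            if noise_sd > 0:
                conc = mean * (1 - mean) / noise_sd**2 - 1
                if conc > 0:
                    real = float(
                        rng.beta(mean * conc, (1 - mean) * conc)
                    )
                else:  # requested noise exceeds the binomial-mean limit
                    real = float(rng.uniform(0, 1) < mean)
            else:
                real = mean
            k = int(rng.binomial(n_reads, real))
            psi.loc[eid, sid] = k / n_reads
            count_rows.append((sid, eid, k, n_reads - k))
            truth_rows.append((sid, eid, mean, real, init, final, ec50, hill))
    counts = pd.DataFrame(
        count_rows, columns=["sample_id", "event", "n_inclusion", "n_exclusion"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "event", "curve_psi", "realized_psi",
            "psi_init", "psi_final", "ec50", "hill",
        ],
    )
    return CohortSim(psi=psi, counts=counts, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# Flank / motif simulation

@dataclass(frozen=True)
class PlantedMotif:
    """A pentamer planted in one region at a positional window.

    ``window`` is a (start, end) half-open offset range for the planted
    occurrence start; ``fg_rate``/``bg_rate`` are per-exon planting
    probabilities in the foreground and background sets.
    """

    pentamer: str
    region: str
    window: tuple[int, int]
    fg_rate: float
    bg_rate: float = 0.0

    def __post_init__(self) -> None:
        pentamer_code(self.pentamer)  # validates alphabet
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        lo, hi = self.window
        if not (0 <= lo < hi <= REGION_LENGTHS[self.region] - 5 + 1):
            raise ValueError(
                f"window {self.window} outside region {self.region} "
                f"({REGION_LENGTHS[self.region]} nt)"
            )
        for rate in (self.fg_rate, self.bg_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("planting rates must be in [0, 1]")


#: Background conservation model: a base is drawn from the conserved
#: component (mean 0.9) with probability 0.25, else the neutral component
#: (mean 0.0); spread 0.25 each.  Planted motif bases are set near 1.2.
_CONS_P_CONSERVED = 0.25


def _background_conservation(rng: np.random.Generator, n: int) -> np.ndarray:
    conserved = rng.random(n) < _CONS_P_CONSERVED
    return rng.normal(0.0, 0.25, n) + conserved * 0.9


def _make_exon(
    rng: np.random.Generator,
    planted: Sequence[PlantedMotif],
    is_foreground: bool,
) -> tuple[dict[str, str], dict[str, np.ndarray], list[tuple[str, str, int]]]:
    seqs: dict[str, str] = {}
    cons: dict[str, np.ndarray] = {}
    for region in REGIONS:
        n = REGION_LENGTHS[region]
        seqs[region] = _random_seq(rng, n)
        cons[region] = _background_conservation(rng, n)
    plants: list[tuple[str, str, int]] = []
    for motif in planted:
        rate = motif.fg_rate if is_foreground else motif.bg_rate
        if rng.random() < rate:
            lo, hi = motif.window
            pos = int(rng.integers(lo, hi))
            seq = seqs[motif.region]
            seqs[motif.region] = seq[:pos] + motif.pentamer + seq[pos + 5 :]
            cons[motif.region][pos : pos + 5] = rng.normal(1.2, 0.05, 5)
            plants.append((motif.pentamer, motif.region, pos))
    return seqs, cons, plants


def simulate_flanks(
    n_foreground: int,
    n_background: int,
    rng: np.random.Generator,
    planted: Sequence[PlantedMotif] = (),
    slopes: Mapping[str, float] | None = None,
    noise_sd: float = 0.02,
    foreground_label: str = "foreground_down",
) -> tuple[list[ExonFlankRecord], list[ExonFlankRecord], pd.DataFrame]:
    """Simulate exon flank records with optional planted conserved motifs.

    ΔPSI for each foreground exon is a linear combination of its conserved
    pentamer counts over the predictive flank regions (200 nt intron +
    50 nt exon per side) using ``slopes`` (pentamer -> ΔPSI per count),
    plus Gaussian noise.  Returns (foreground, background, truth).
    """
    slopes = dict(slopes or {})
    fg_records: list[ExonFlankRecord] = []
    bg_records: list[ExonFlankRecord] = []
    truth_rows = []

    for i in range(n_foreground):
        exon_id = f"fg_{i+1:04d}"
        seqs, cons, plants = _make_exon(rng, planted, True)
        base = ExonFlankRecord(exon_id, foreground_label, seqs, cons, delta_psi=0.0)
        delta = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        if slopes:
            up, down = _flank_counts([base], 0.5, 200, 50)
            for pent, slope in slopes.items():
                code = pentamer_code(pent)
                delta += slope * float(up[0, code] + down[0, code])
        rec = ExonFlankRecord(exon_id, foreground_label, seqs, cons, delta_psi=delta)
        fg_records.append(rec)
        for pent, region, pos in plants:
            truth_rows.append((exon_id, foreground_label, pent, region, pos))
    for i in range(n_background):
        exon_id = f"bg_{i+1:04d}"
        seqs, cons, plants = _make_exon(rng, planted, False)
        bg_records.append(ExonFlankRecord(exon_id, "background", seqs, cons))
        for pent, region, pos in plants:
            truth_rows.append((exon_id, "background", pent, region, pos))
    truth = pd.DataFrame(
        truth_rows, columns=["exon_id", "set", "pentamer", "region", "offset"]
    )
    return fg_records, bg_records, truth


# ---------------------------------------------------------------------------
# mdx comparison table

#: Events with a splicing response to chronic myopathy/regeneration in the
#: dystrophic (mdx) model; only these exceed a 10-percentage-point shift.
MDX_SHIFTED: Mapping[str, float] = {
    "Clasp1": 0.16,
    "Eya4": -0.18,
    "Opa1": 0.14,
    "Trim55": -0.20,
}


def mdx_psi_table(
    rng: np.random.Generator,
    n_wt: int = 6,
    n_mdx: int = 6,
    noise_sd: float = 0.015,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSI matrix for a dystrophic (mdx) vs wild-type quadriceps cohort.

    The four myopathy-responsive events shift by 14-20 percentage points;
    all other panel events drift by at most ~4 points.  Returns (psi,
    sample sheet).
    """
    panel = synthetic_panel()
    genes = [e.event_id for e in panel.events]
    sample_rows = [(f"WT_{i+1:02d}", "WT", "quadriceps") for i in range(n_wt)]
    sample_rows += [(f"mdx_{i+1:02d}", "mdx", "quadriceps") for i in range(n_mdx)]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group", "tissue"])
    psi = pd.DataFrame(index=genes, columns=samples["sample_id"], dtype=float)
    for gene in genes:
        base = float(rng.uniform(0.2, 0.8))
        shift = MDX_SHIFTED.get(gene, float(rng.uniform(-0.04, 0.04)))
        for sid, group in zip(samples["sample_id"], samples["group"]):
            mean = base + (shift if group == "mdx" else 0.0)
            psi.loc[gene, sid] = float(np.clip(rng.normal(mean, noise_sd), 0.0, 1.0))
    return psi, samples
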