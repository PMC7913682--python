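"""Isoform-specific read counting and PSI estimation for amplicon reads.

Each splice event is represented by two reference sequences: the inclusion
isoform (upstream flank + cassette exon + downstream flank) and the
exclusion isoform (flanks joined directly).  Reads aligned against this
two-sequence reference are informative only if their primary alignment
spans a splice junction of the best-matching isoform with sufficient
overhang and beats the other isoform's alignment score.  Percent spliced
in (PSI) is the fraction of inclusion-isoform reads among all informative
(inclusion + exclusion) reads, with a Clopper-Pearson binomial confidence
interval.

Detection bias of the targeted assay relative to an orthogonal PSI source
(e.g. conventional RNA-seq) is summarized as the per-event and overall
mean difference in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SpliceEvent

__all__ = [
    "IsoformReference",
    "AlignmentRecord",
    "ClassifiedRead",
    "IsoformCounts",
    "PsiEstimate",
    "build_isoform_refs",
    "classify_reads",
    "count_and_psi",
    "detection_bias",
    "align_reads_exact",
    "read_alignments_sam",
    "write_isoform_fasta",
]

INCLUSION = "inclusion"
EXCLUSION = "exclusion"
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class IsoformReference:
    """Inclusion/exclusion reference sequences for one splice event.

    Junction offsets are 0-based positions *between* bases: the inclusion
    isoform has junctions where the upstream flank meets the cassette and
    where the cassette meets the downstream flank; the exclusion isoform
    has the single skipping junction where the flanks meet.
    """

    event: SpliceEvent
    inclusion_seq: str
    exclusion_seq: str
    inclusion_junctions: tuple[int, int]
    exclusion_junction: int

    def junctions(self, target: str) -> tuple[int, ...]:
        if target == INCLUSION:
            return self.inclusion_junctions
        if target == EXCLUSION:
            return (self.exclusion_junction,)
        raise ValueError(f"unknown isoform target {target!r}")

    def sequence(self, target: str) -> str:
        return self.inclusion_seq if target == INCLUSION else self.exclusion_seq


def build_isoform_refs(
    event: SpliceEvent,
    flank_up_seq: str,
    cassette_seq: str,
    flank_down_seq: str,
) -> IsoformReference:
    """Construct the two isoform references from flank and cassette sequence.

    All sequences must be supplied in transcript (sense) orientation;
    minus-strand genes are reverse-complemented upstream of this call.
    """
    for name, seq in (
        ("upstream flank", flank_up_seq),
        ("cassette", cassette_seq),
        ("downstream flank", flank_down_seq),
    ):
        if not seq:
            raise ValueError(f"{event.event_id}: empty {name} sequence")
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"{event.event_id}: {name} has non-ACGTN characters")
    if len(cassette_seq) != event.cassette_len:
        raise ValueError(
            f"{event.event_id}: cassette sequence length {len(cassette_seq)} != "
            f"declared cassette_len {event.cassette_len}"
        )
    total = flank_up_seq + cassette_seq + flank_down_seq
    n_frac = total.count("N") / len(total)
    if n_frac > 0.10:
        import warnings

        warnings.warn(
            f"{event.event_id}: {n_frac:.0%} ambiguous (N) bases in reference",
            stacklevel=2,
        )
    j1 = len(flank_up_seq)
    j2 = j1 + len(cassette_seq)
    return IsoformReference(
        event=event,
        inclusion_seq=total,
        exclusion_seq=flank_up_seq + flank_down_seq,
        inclusion_junctions=(j1, j2),
        exclusion_junction=j1,
    )


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a read (or mate) to one isoform reference."""

    read_id: str
    target: str  # INCLUSION or EXCLUSION
    score: float
    primary: bool
    ref_start: int  # 0-based half-open aligned span on the reference
    ref_end: int


@dataclass(frozen=True)
class ClassifiedRead:
    """Classification outcome for one read (or read pair / fragment)."""

    read_id: str
    best_target: str
    primary: bool
    spans_junction: bool
    score_margin: float


def _spans(rec_start: int, rec_end: int, junction: int, min_overhang: int) -> bool:
    return (junction - rec_start) >= min_overhang and (rec_end - junction) >= min_overhang


def classify_reads(
    alignments: Iterable[AlignmentRecord],
    ref: IsoformReference,
    min_overhang: int = 8,
) -> list[ClassifiedRead]:
    """Classify reads as inclusion, exclusion, ambiguous or uninformative.

    A read is informative for an isoform iff (i) it has a primary alignment
    to that isoform, (ii) the aligned span covers one of that isoform's
    splice junctions with at least ``min_overhang`` nt on each side, and
    (iii) its alignment score strictly beats the score on the other isoform
    (``score_margin > 0``).  Equal best scores with a junction spanned on
    either isoform yield ``ambiguous``; reads spanning no junction are
    ``uninformative``.  Records sharing a ``read_id`` (paired-end mates)
    are merged: per-isoform the best mate score is used and junction
    coverage by either mate counts, so conflicting mate evidence collapses
    to ``ambiguous``.
    """
    valid_targets = (INCLUSION, EXCLUSION)
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        if rec.target not in valid_targets:
            raise ValueError(f"read {rec.read_id} aligned to unknown reference {rec.target!r}")
        by_read.setdefault(rec.read_id, []).append(rec)

    out: list[ClassifiedRead] = []
    for read_id, recs in by_read.items():
        primaries = [r for r in recs if r.primary]
        if not primaries:
            out.append(ClassifiedRead(read_id, UNINFORMATIVE, False, False, 0.0))
            continue
        score: dict[str, float] = {}
        spans: dict[str, bool] = {}
        for r in primaries:
            score[r.target] = max(score.get(r.target, -np.inf), r.score)
            spans[r.target] = spans.get(r.target, False) or any(
                _spans(r.ref_start, r.ref_end, j, min_overhang)
                for j in ref.junctions(r.target)
            )
        targets = sorted(score, key=lambda t: (-score[t], t))
        best = targets[0]
        margin = (
            score[best] - score[targets[1]] if len(targets) > 1 else float("inf")
        )
        if margin > 0:
            if spans[best]:
                out.append(ClassifiedRead(read_id, best, True, True, margin))
            else:
                out.append(ClassifiedRead(read_id, UNINFORMATIVE, True, False, margin))
        else:
            if any(spans.values()):
                out.append(ClassifiedRead(read_id, AMBIGUOUS, True, True, 0.0))
            else:
                out.append(ClassifiedRead(read_id, UNINFORMATIVE, True, False, 0.0))
    return out


@dataclass(frozen=True)
class IsoformCounts:
    event_id: str
    sample_id: str
    n_inclusion: int
    n_exclusion: int
    n_ambiguous: int
    n_uninformative: int

    @property
    def n_informative(self) -> int:
        return self.n_inclusion + self.n_exclusion

    @property
    def total(self) -> int:
        return self.n_informative + self.n_ambiguous + self.n_uninformative


@dataclass(frozen=True)
class PsiEstimate:
    """PSI with a Clopper-Pearson 95% interval; undefined below min_reads."""

    psi: float | None
    n_informative: int
    ci_low: float | None
    ci_high: float | None
    defined: bool


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if n == 0:
        raise ValueError("n must be > 0")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def count_and_psi(
    classified: Sequence[ClassifiedRead],
    min_reads: int = 20,
    event_id: str = ".",
    sample_id: str = ".",
) -> tuple[IsoformCounts, PsiEstimate]:
    """Tally classified reads for one event/sample and estimate PSI.

    PSI = n_inclusion / (n_inclusion + n_exclusion).  The estimate is
    flagged undefined when fewer than ``min_reads`` informative reads are
    available (counts are still reported).
    """
    n_inc = sum(1 for c in classified if c.best_target == INCLUSION)
    n_exc = sum(1 for c in classified if c.best_target == EXCLUSION)
    n_amb = sum(1 for c in classified if c.best_target == AMBIGUOUS)
    n_uninf = sum(1 for c in classified if c.best_target == UNINFORMATIVE)
    counts = IsoformCounts(event_id, sample_id, n_inc, n_exc, n_amb, n_uninf)
    n = counts.n_informative
    if n < min_reads:
        return counts, PsiEstimate(None, n, None, None, False)
    low, high = clopper_pearson(n_inc, n)
    return counts, PsiEstimate(n_inc / n, n, low, high, True)


def detection_bias(
    psi_targeted: pd.DataFrame,
    psi_reference: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Compare targeted PSI against an orthogonal reference PSI source.

    Both inputs are event x sample matrices on the [0, 1] scale.  Returns a
    per-event table with the mean difference (targeted - reference) in
    percentage points, and the overall mean over all defined event/sample
    pairs.  Negative values indicate under-detection of exon inclusion by
    the targeted assay.
    """
    events = psi_targeted.index.intersection(psi_reference.index)
    samples = psi_targeted.columns.intersection(psi_reference.columns)
    if len(events) == 0 or len(samples) == 0:
        raise ValueError("no overlapping events/samples between PSI matrices")
    delta = (
        psi_targeted.loc[events, samples] - psi_reference.loc[events, samples]
    ) * 100.0
    per_event = pd.DataFrame(
        {
            "mean_delta_psi_pct": delta.mean(axis=1, skipna=True),
            "n_pairs": delta.notna().sum(axis=1),
        }
    )
    overall = float(np.nanmean(delta.to_numpy(dtype=float)))
    return per_event, overall


# ---------------------------------------------------------------------------
# Alignment input

def align_reads_exact(
    reads: Iterable[tuple[str, str]],
    ref: IsoformReference,
) -> list[AlignmentRecord]:
    """Exact-substring aligner for error-free reads.

    A minimal aligner for simulator output: each read is located by exact
    substring search on both isoform references; the score is the read
    length, so a read present in both references (entirely within a shared
    flank) ties.  Not a general-purpose aligner.
    """
    records: list[AlignmentRecord] = []
    for read_id, seq in reads:
        for target in (INCLUSION, EXCLUSION):
            pos = ref.sequence(target).find(seq)
            if pos >= 0:
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        target=target,
                        score=float(len(seq)),
                        primary=True,
                        ref_start=pos,
                        ref_end=pos + len(seq),
                    )
                )
    return records


def _parse_ref_name(name: str) -> tuple[str, str]:
    """Split `<event_id>__inc` / `<event_id>__exc` reference names."""
    if name.endswith("__inc"):
        return name[:-5], INCLUSION
    if name.endswith("__exc"):
        return name[:-5], EXCLUSION
    raise ValueError(f"unrecognized isoform reference name {name!r}")


def read_alignments_sam(path: str | Path) -> dict[str, list[AlignmentRecord]]:
    """Read SAM/BAM alignments grouped per event.

    Reference sequence names must follow the `<event_id>__inc` /
    `<event_id>__exc` convention.  The alignment score is taken from the
    ``AS`` tag when present, otherwise the number of aligned reference
    bases.  Secondary and supplementary alignments are retained but flagged
    non-primary.
    """
    import pysam

    per_event: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            event_id, target = _parse_ref_name(aln.reference_name)
            score = (
                float(aln.get_tag("AS"))
                if aln.has_tag("AS")
                else float(aln.reference_length or 0)
            )
            per_event.setdefault(event_id, []).append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target=target,
                    score=score,
                    primary=not (aln.is_secondary or aln.is_supplementary),
                    ref_start=aln.reference_start,
                    ref_end=aln.reference_end,
                )
            )
    return per_event


def write_isoform_fasta(refs: Iterable[IsoformReference], path: str | Path) -> None:
    """Write isoform references as `<event_id>__inc` / `__exc` FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for ref in refs:
        eid = ref.event.event_id
        records.append(SeqRecord(Seq(ref.inclusion_seq), id=f"{eid}__inc", description=""))
        records.append(SeqRecord(Seq(ref.exclusion_seq), id=f"{eid}__exc", description=""))
    SeqIO.write(records, str(path), "fasta")


def psi_table(
    counts: Iterable[tuple[IsoformCounts, PsiEstimate]],
) -> pd.DataFrame:
    """Long-format counts/PSI table (one row per event x sample)."""
    rows = []
    for c, p in counts:
        rows.append(
            dict(
                sample=c.sample_id, event=c.event_id, n_inclusion=c.n_inclusion,
                n_exclusion=c.n_exclusion, n_ambiguous=c.n_ambiguous,
                n_uninformative=c.n_uninformative, psi=p.psi,
                ci_low=p.ci_low, ci_high=p.ci_high,
            )
        )
    return pd.DataFrame(rows)
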