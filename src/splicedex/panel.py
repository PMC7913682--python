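"""Targeted splice panel: event/amplicon models and design validation.

A targeted splice-sequencing panel consists of cassette-exon alternative
splicing events, each assayed by a single RT-PCR amplicon that spans the
alternative exon.  Because the exon-inclusion and exon-exclusion products
share primers, the inclusion amplicon is longer by exactly the cassette
length; designs aim to keep the cassette a small fraction of the amplicon
so that the two products amplify with near-equal efficiency.

This module validates supplied designs against the assay's design rules
(it does not design primers):

* one primer must end within 125 nt of the cassette exon, so that short
  sequencing reads capture the informative splice junctions;
* amplicons should be at least 400 bp where possible (advisory);
* primer sets are distributed across four first-stage multiplex PCR pools
  (A, B, C, D with 17, 15, 13 and 12 cycles) so that highly expressed
  transcripts receive fewer cycles, balancing read counts across events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SpliceEvent",
    "AmpliconDesign",
    "PanelRecord",
    "PanelSummary",
    "POOL_CYCLES",
    "check_amplicon",
    "summarize_panel",
    "assign_pools",
    "read_panel",
    "write_panel_report",
]

#: First-stage multiplex PCR cycle count for each pool label.
POOL_CYCLES: Mapping[str, int] = {"A": 17, "B": 15, "C": 13, "D": 12}

#: Pools ordered from fewest to most cycles; high-abundance events go first.
_POOLS_BY_CYCLES = sorted(POOL_CYCLES, key=lambda p: POOL_CYCLES[p])  # D, C, B, A

_VALID_ROLES = ("test", "negative_control")
_VALID_PRIMER_CONC = (50, 200)
_DNA = set("ACGT")


class InvalidDesignError(ValueError):
    """Raised when an amplicon design violates its structural invariants."""


@dataclass(frozen=True)
class SpliceEvent:
    """One cassette-exon alternative splicing event.

    Coordinates are 0-based half-open genomic coordinates of the cassette
    exon; ``role`` distinguishes disease-responsive test events from the
    negative control (at most one per panel).
    """

    event_id: str
    gene: str
    cassette_len: int
    chrom: str = "."
    start: int = 0
    end: int = 0
    strand: str = "+"
    role: str = "test"

    def __post_init__(self) -> None:
        if self.cassette_len <= 0:
            raise ValueError(f"{self.event_id}: cassette_len must be > 0")
        if self.end or self.start:
            if self.end - self.start != self.cassette_len:
                raise ValueError(
                    f"{self.event_id}: end - start ({self.end - self.start}) "
                    f"!= cassette_len ({self.cassette_len})"
                )
        else:
            # no genomic coordinates supplied; synthesize a consistent interval
            object.__setattr__(self, "end", self.start + self.cassette_len)
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: strand must be + or -")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"{self.event_id}: role must be one of {_VALID_ROLES}")


@dataclass(frozen=True)
class AmpliconDesign:
    """A primer pair and the two isoform amplicons it produces.

    ``fwd_distance``/``rev_distance`` are measured on the inclusion isoform
    from each primer's 3' terminus to the nearest cassette-exon boundary.
    """

    event: SpliceEvent
    fwd_primer: str
    rev_primer: str
    fwd_distance: int
    rev_distance: int
    inclusion_len: int
    exclusion_len: int
    pool: str = "B"
    primer_conc: int = 200

    def __post_init__(self) -> None:
        if self.inclusion_len != self.exclusion_len + self.event.cassette_len:
            raise InvalidDesignError(
                f"{self.event.event_id}: inclusion_len ({self.inclusion_len}) != "
                f"exclusion_len ({self.exclusion_len}) + cassette_len "
                f"({self.event.cassette_len})"
            )
        if self.exclusion_len <= 0:
            raise InvalidDesignError(
                f"{self.event.event_id}: exclusion amplicon length must be > 0"
            )
        for name, primer in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if len(primer) < 15:
                raise InvalidDesignError(
                    f"{self.event.event_id}: {name} primer shorter than 15 nt"
                )
            if not set(primer) <= _DNA:
                raise InvalidDesignError(
                    f"{self.event.event_id}: {name} primer has non-ACGT characters"
                )
        if self.pool not in POOL_CYCLES:
            raise InvalidDesignError(f"{self.event.event_id}: unknown pool {self.pool!r}")
        if self.primer_conc not in _VALID_PRIMER_CONC:
            raise InvalidDesignError(
                f"{self.event.event_id}: primer_conc must be one of {_VALID_PRIMER_CONC} nM"
            )

    @property
    def pool_cycles(self) -> int:
        return POOL_CYCLES[self.pool]

    @property
    def exon_fraction(self) -> float:
        """Fraction of the inclusion amplicon occupied by the cassette exon."""
        return self.event.cassette_len / self.inclusion_len


@dataclass(frozen=True)
class PanelRecord:
    """Validation record for a single amplicon design."""

    event_id: str
    exon_fraction: float
    length_ok: bool
    proximity_ok: bool
    warnings: tuple[str, ...] = ()


def check_amplicon(design: AmpliconDesign) -> PanelRecord:
    """Validate one amplicon design against the panel design rules.

    ``length_ok`` (inclusion amplicon >= 400 bp) is advisory and failure is
    reported as a warning; ``proximity_ok`` (either primer 3' end strictly
    less than 125 nt from the cassette exon) is a hard requirement flag.
    """
    warnings: list[str] = []
    length_ok = design.inclusion_len >= 400
    if not length_ok:
        warnings.append(
            f"inclusion amplicon {design.inclusion_len} bp below the 400 bp target"
        )
    proximity_ok = min(design.fwd_distance, design.rev_distance) < 125
    if not proximity_ok:
        warnings.append(
            "neither primer ends within 125 nt of the cassette exon; "
            "junction reads may have low quality base calls"
        )
    return PanelRecord(
        event_id=design.event.event_id,
        exon_fraction=design.exon_fraction,
        length_ok=length_ok,
        proximity_ok=proximity_ok,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class PanelSummary:
    """Panel-level summary statistics (percentages on a 0-100 scale).

    Standard deviations are sample (n-1) standard deviations; ``nan`` for a
    single-design panel.
    """

    n_designs: int
    exon_fraction_mean_pct: float
    exon_fraction_sd_pct: float
    inclusion_len_mean: float
    inclusion_len_sd: float
    pool_counts: Mapping[str, int]
    sd_kind: str = "sample (ddof=1)"


def summarize_panel(designs: Sequence[AmpliconDesign]) -> PanelSummary:
    """Summarize exon fractions, amplicon lengths and pool membership."""
    if len(designs) == 0:
        raise ValueError("cannot summarize an empty panel")
    fractions = pd.Series([d.exon_fraction for d in designs], dtype=float)
    lengths = pd.Series([d.inclusion_len for d in designs], dtype=float)
    pool_counts = {p: 0 for p in POOL_CYCLES}
    for d in designs:
        pool_counts[d.pool] += 1
    return PanelSummary(
        n_designs=len(designs),
        exon_fraction_mean_pct=100.0 * fractions.mean(),
        exon_fraction_sd_pct=100.0 * fractions.std(ddof=1),
        inclusion_len_mean=lengths.mean(),
        inclusion_len_sd=lengths.std(ddof=1),
        pool_counts=pool_counts,
    )


def _balanced_quartiles(n: int) -> list[int]:
    """Sizes of 4 contiguous rank bins differing by at most one."""
    base, extra = divmod(n, 4)
    return [base + (1 if i < extra else 0) for i in range(4)]


def assign_pools(
    designs: Sequence[AmpliconDesign],
    abundance: Mapping[str, float],
    dimer_conflicts: Iterable[frozenset[str]] = (),
) -> dict[str, str]:
    """Assign events to the four PCR pools by abundance rank quartiles.

    Events are ranked by relative transcript abundance (descending, ties
    broken by ``event_id``) and split into four near-equal rank bins; the
    most abundant quartile is assigned to the lowest-cycle pool (D, 12
    cycles) and the least abundant to the highest (A, 17 cycles).  Pairs of
    primer sets known to form primer-dimers must not share a pool; a
    conflicting member is displaced to the nearest pool (by cycle count)
    without conflict.  Deterministic given the inputs.
    """
    ids = [d.event.event_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate event_ids in panel")
    for eid in ids:
        if eid not in abundance:
            raise ValueError(f"no abundance supplied for event {eid}")
        if abundance[eid] <= 0:
            raise ValueError(f"abundance must be > 0 (event {eid})")

    conflicts = {frozenset(c) for c in dimer_conflicts}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for pair in conflicts:
        a, b = sorted(pair)
        if a in graph and b in graph:
            graph.add_edge(a, b)

    # a clique of >4 mutually conflicting primer sets cannot be 4-colored
    for clique in nx.find_cliques(graph):
        if len(clique) > 4:
            raise ValueError(
                "unsatisfiable primer-dimer conflicts; mutually conflicting "
                f"events: {sorted(clique)}"
            )

    order = sorted(ids, key=lambda e: (-abundance[e], e))
    assignment: dict[str, str] = {}
    pos = 0
    for pool, size in zip(_POOLS_BY_CYCLES, _balanced_quartiles(len(order))):
        for eid in order[pos : pos + size]:
            assignment[eid] = pool
        pos += size

    def conflicted(eid: str) -> bool:
        return any(assignment[nb] == assignment[eid] for nb in graph.neighbors(eid))

    # displace the less abundant member of each conflicting pair to the
    # nearest conflict-free pool (smallest cycle-count change first)
    for _ in range(4 * len(order) + 4):
        pair = next(
            (
                tuple(sorted(p, key=lambda e: (-abundance[e], e)))
                for p in sorted(map(sorted, graph.edges()))
                if assignment[p[0]] == assignment[p[1]]
            ),
            None,
        )
        if pair is None:
            break
        mover = pair[1]  # lower abundance (or later id) moves
        home = POOL_CYCLES[assignment[mover]]
        candidates = sorted(
            (p for p in POOL_CYCLES if p != assignment[mover]),
            key=lambda p: (abs(POOL_CYCLES[p] - home), POOL_CYCLES[p]),
        )
        for pool in candidates:
            if all(assignment[nb] != pool for nb in graph.neighbors(mover)):
                assignment[mover] = pool
                break
        else:
            raise ValueError(
                f"could not place event {mover}; conflicting events: "
                f"{sorted(graph.neighbors(mover))}"
            )
    else:
        raise ValueError("pool assignment did not converge under the conflict set")
    return assignment


# ---------------------------------------------------------------------------
# TSV interfaces

_PANEL_COLUMNS = [
    "event_id", "gene", "chrom", "start", "end", "strand", "role",
    "fwd_primer", "rev_primer", "fwd_distance", "rev_distance",
    "inclusion_len", "exclusion_len", "pool", "primer_conc",
]


def read_panel(path: str | Path) -> list[AmpliconDesign]:
    """Read a panel definition TSV into :class:`AmpliconDesign` objects."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing columns: {missing}")
    designs = []
    for row in df.itertuples(index=False):
        event = SpliceEvent(
            event_id=str(row.event_id),
            gene=str(row.gene),
            cassette_len=int(row.end) - int(row.start),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            role=str(row.role),
        )
        designs.append(
            AmpliconDesign(
                event=event,
                fwd_primer=str(row.fwd_primer),
                rev_primer=str(row.rev_primer),
                fwd_distance=int(row.fwd_distance),
                rev_distance=int(row.rev_distance),
                inclusion_len=int(row.inclusion_len),
                exclusion_len=int(row.exclusion_len),
                pool=str(row.pool),
                primer_conc=int(row.primer_conc),
            )
        )
    return designs


def panel_to_frame(designs: Sequence[AmpliconDesign]) -> pd.DataFrame:
    """Serialize designs to the panel TSV column layout."""
    rows = []
    for d in designs:
        e = d.event
        rows.append(
            dict(
                event_id=e.event_id, gene=e.gene, chrom=e.chrom, start=e.start,
                end=e.end, strand=e.strand, role=e.role, fwd_primer=d.fwd_primer,
                rev_primer=d.rev_primer, fwd_distance=d.fwd_distance,
                rev_distance=d.rev_distance, inclusion_len=d.inclusion_len,
                exclusion_len=d.exclusion_len, pool=d.pool, primer_conc=d.primer_conc,
            )
        )
    return pd.DataFrame(rows, columns=_PANEL_COLUMNS)


def write_panel_report(designs: Sequence[AmpliconDesign], path: str | Path) -> pd.DataFrame:
    """Run :func:`check_amplicon` over a panel and write a report TSV."""
    records = [check_amplicon(d) for d in designs]
    df = pd.DataFrame(
        dict(
            event_id=[r.event_id for r in records],
            exon_fraction=[r.exon_fraction for r in records],
            length_ok=[r.length_ok for r in records],
            proximity_ok=[r.proximity_ok for r in records],
            warnings=["; ".join(r.warnings) for r in records],
        )
    )
    df.to_csv(path, sep="\t", index=False)
    return df
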