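"""Conserved-pentamer positional enrichment and ΔPSI linear-model ranking.

Splicing-factor binding sites are short degenerate motifs whose position
relative to a regulated cassette exon determines the splicing outcome
(e.g. MBNL YGCY sites downstream of an exon promote inclusion in mature
muscle, so their loss of regulation shows up as position-specific motif
enrichment around disease-affected exons).  Two complementary analyses
are implemented over four regions flanking each exon — 350 nt of upstream
intron, 50 nt of exon on each edge, and 350 nt of downstream intron, all
in sense orientation:

* **Positional enrichment** — for every pentamer and every 50-nt sliding
  window, exons in a foreground set (splicing-affected) are compared with
  a background set (alternatively spliced but unaffected) by presence of
  at least one *conserved* occurrence (mean per-base phyloP >= 0.5 over
  the 5 bases) starting in the window; significance by two-sided Fisher
  exact test with Benjamini-Hochberg correction over the whole
  pentamer x position family.

* **Predictive ranking** — per pentamer, an ordinary least squares model
  ΔPSI ~ upstream conserved count + downstream conserved count (counts
  over 200 nt of intron plus 50 nt of exon on each side), ranked by
  adjusted R².

Sequences are handled in the DNA alphabet; report pentamers in the RNA
alphabet with :func:`dna_to_rna` at the presentation layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExonFlankRecord",
    "PentamerOccurrence",
    "REGIONS",
    "REGION_LENGTHS",
    "scan_pentamers",
    "window_enrichment",
    "rank_pentamers",
    "benjamini_hochberg",
    "dna_to_rna",
    "all_pentamers",
]

K = 5
PHYLOP_MIN = 0.5
#: Regions flanking a cassette exon, 5' to 3' in sense orientation.
REGIONS = (
    "upstream_intron",
    "upstream_exon_edge",
    "downstream_exon_edge",
    "downstream_intron",
)
#: Declared region lengths (nt): 350 intron / 50 exon on each side.
REGION_LENGTHS: Mapping[str, int] = {
    "upstream_intron": 350,
    "upstream_exon_edge": 50,
    "downstream_exon_edge": 50,
    "downstream_intron": 350,
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_CODE_POWS = 4 ** np.arange(K - 1, -1, -1)


def all_pentamers() -> list[str]:
    """All 1024 DNA pentamers in lexicographic order (code order)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=K)]


_PENTAMERS = all_pentamers()


def dna_to_rna(motif: str) -> str:
    """Present a DNA motif in the RNA alphabet (T -> U)."""
    return motif.replace("T", "U")


def pentamer_code(pentamer: str) -> int:
    code = 0
    for b in pentamer:
        v = _BASE_CODE[b]
        if v < 0:
            raise ValueError(f"ambiguous base in pentamer {pentamer!r}")
        code = code * 4 + v
    return code


@dataclass(frozen=True)
class ExonFlankRecord:
    """Flanking sequence + conservation for one cassette exon.

    ``set_label`` is one of foreground_up (increased inclusion),
    foreground_down (decreased inclusion) or background.  ``sequences``
    and ``conservation`` map region name to sequence / per-base phyloP
    (equal lengths).  Regions may be shorter than declared near short
    introns; ``truncated`` flags that case.  ``delta_psi`` is required for
    foreground records used in ranking.
    """

    exon_id: str
    set_label: str
    sequences: Mapping[str, str]
    conservation: Mapping[str, np.ndarray]
    delta_psi: float | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        for region in REGIONS:
            if region not in self.sequences:
                raise ValueError(f"{self.exon_id}: missing region {region}")
            seq = self.sequences[region]
            cons = np.asarray(self.conservation[region], dtype=float)
            if len(cons) != len(seq):
                raise ValueError(
                    f"{self.exon_id}/{region}: conservation track length "
                    f"{len(cons)} != sequence length {len(seq)}"
                )


def _encode(seq: str) -> np.ndarray:
    """Per-position pentamer codes (-1 where the window touches an N)."""
    arr = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    n = len(arr) - K + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, K)
    codes = windows @ _CODE_POWS
    codes[(windows < 0).any(axis=1)] = -1
    return codes


def _mean_phylop(cons: np.ndarray) -> np.ndarray:
    """Rolling mean of the conservation track over K-base windows."""
    cons = np.asarray(cons, dtype=float)
    if len(cons) < K:
        return np.empty(0)
    return np.convolve(cons, np.ones(K) / K, mode="valid")


@dataclass(frozen=True)
class PentamerOccurrence:
    pentamer: str
    exon_id: str
    region: str
    offset: int
    mean_phylop: float
    conserved: bool


def scan_pentamers(
    record: ExonFlankRecord,
    phylop_min: float = PHYLOP_MIN,
) -> list[PentamerOccurrence]:
    """Enumerate every pentamer occurrence in every region of one exon.

    Overlapping occurrences are all emitted; positions whose 5-base window
    contains an N yield no occurrence.  The conserved flag requires mean
    phyloP >= ``phylop_min`` over the occurrence's 5 bases.
    """
    out: list[PentamerOccurrence] = []
    for region in REGIONS:
        codes = _encode(record.sequences[region])
        means = _mean_phylop(record.conservation[region])
        for offset, code in enumerate(codes):
            if code < 0:
                continue
            mp = float(means[offset])
            out.append(
                PentamerOccurrence(
                    pentamer=_PENTAMERS[code],
                    exon_id=record.exon_id,
                    region=region,
                    offset=offset,
                    mean_phylop=mp,
                    conserved=mp >= phylop_min,
                )
            )
    return out


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _conserved_start_matrix(
    records: Sequence[ExonFlankRecord],
    region: str,
    phylop_min: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """(codes, conserved) matrices [n_exons, n_positions] padded with -1/False."""
    n = len(records)
    length = max(len(r.sequences[region]) for r in records)
    n_pos = max(length - K + 1, 0)
    codes = np.full((n, n_pos), -1, dtype=np.int64)
    cons = np.zeros((n, n_pos), dtype=bool)
    for i, rec in enumerate(records):
        c = _encode(rec.sequences[region])
        m = _mean_phylop(rec.conservation[region])
        codes[i, : len(c)] = c
        cons[i, : len(c)] = m >= phylop_min
    return codes, cons, length


def _fisher_lookup(n_fg: int, n_bg: int) -> np.ndarray:
    """Two-sided Fisher exact p for every (a, c) table with fixed group sizes.

    Table: [[a, n_fg - a], [c, n_bg - c]].  Returns array P[a, c].
    """
    P = np.empty((n_fg + 1, n_bg + 1))
    for a in range(n_fg + 1):
        for c in range(n_bg + 1):
            P[a, c] = stats.fisher_exact(
                [[a, n_fg - a], [c, n_bg - c]], alternative="two-sided"
            )[1]
    return P


def window_enrichment(
    foreground: Sequence[ExonFlankRecord],
    background: Sequence[ExonFlankRecord],
    window: int = 50,
    step: int = 1,
    phylop_min: float = PHYLOP_MIN,
    pentamers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Positional conserved-pentamer enrichment of foreground vs background.

    For each pentamer, region and window start position, exons are scored
    for presence of at least one conserved occurrence whose start offset
    lies in [w, w + window); the 2x2 exon-count table (foreground/
    background x with/without) is tested by two-sided Fisher exact test.
    Fold enrichment is the ratio of with-fractions (NaN when both are 0,
    inf when only the background fraction is 0).  BH correction is applied
    across the full pentamer x region x position family of this call;
    run separate calls for increased- vs decreased-inclusion foregrounds.

    Returns a long DataFrame with columns pentamer, region, window_start,
    fg_with, bg_with, fold_enrichment, p, q.
    """
    if not foreground or not background:
        raise ValueError("foreground and background sets must be non-empty")
    n_fg, n_bg = len(foreground), len(background)
    pent_codes = (
        np.arange(len(_PENTAMERS))
        if pentamers is None
        else np.array(sorted(pentamer_code(p) for p in pentamers))
    )
    lookup = _fisher_lookup(n_fg, n_bg)

    frames = []
    for region in REGIONS:
        fg_codes, fg_cons, fg_len = _conserved_start_matrix(foreground, region, phylop_min)
        bg_codes, bg_cons, bg_len = _conserved_start_matrix(background, region, phylop_min)
        length = max(fg_len, bg_len)
        if window > length:
            raise ValueError(
                f"window ({window}) longer than region {region} ({length} nt)"
            )
        starts = np.arange(0, length - window + 1, step)

        def _with_counts(codes: np.ndarray, cons: np.ndarray, code: int) -> np.ndarray:
            occ = (codes == code) & cons
            cs = np.zeros((occ.shape[0], occ.shape[1] + 1), dtype=np.int32)
            np.cumsum(occ, axis=1, out=cs[:, 1:])
            his = np.minimum(starts + window, occ.shape[1])
            los = np.minimum(starts, occ.shape[1])
            present = (cs[:, his] - cs[:, los]) > 0
            return present.sum(axis=0)

        for code in pent_codes:
            a = _with_counts(fg_codes, fg_cons, code)
            c = _with_counts(bg_codes, bg_cons, code)
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = (a / n_fg) / (c / n_bg)
            frames.append(
                pd.DataFrame(
                    {
                        "pentamer": _PENTAMERS[code],
                        "region": region,
                        "window_start": starts,
                        "fg_with": a,
                        "bg_with": c,
                        "fold_enrichment": fold,
                        "p": lookup[a, c],
                    }
                )
            )
    result = pd.concat(frames, ignore_index=True)
    result["q"] = benjamini_hochberg(result["p"].to_numpy())
    return result


def _flank_counts(
    records: Sequence[ExonFlankRecord],
    phylop_min: float,
    intron_len: int,
    exon_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Conserved pentamer counts per exon for the upstream/downstream sides.

    Upstream side: the ``intron_len`` intronic nt adjacent to the exon
    (i.e. the 3' end of the upstream intron) plus ``exon_len`` nt of exon;
    downstream side: ``exon_len`` nt of exon plus the first ``intron_len``
    intronic nt.  Counts are per pentamer (1024 columns).
    """
    n = len(records)
    up = np.zeros((n, len(_PENTAMERS)), dtype=np.int64)
    down = np.zeros((n, len(_PENTAMERS)), dtype=np.int64)

    def _count_into(out_row: np.ndarray, seq: str, cons: np.ndarray) -> None:
        codes = _encode(seq)
        if len(codes) == 0:
            return
        keep = (codes >= 0) & (_mean_phylop(cons) >= phylop_min)
        np.add.at(out_row, codes[keep], 1)

    for i, rec in enumerate(records):
        ui = rec.sequences["upstream_intron"][-intron_len:]
        ui_c = np.asarray(rec.conservation["upstream_intron"])[-intron_len:]
        _count_into(up[i], ui, ui_c)
        _count_into(
            up[i],
            rec.sequences["upstream_exon_edge"][:exon_len],
            np.asarray(rec.conservation["upstream_exon_edge"])[:exon_len],
        )
        _count_into(
            down[i],
            rec.sequences["downstream_exon_edge"][-exon_len:],
            np.asarray(rec.conservation["downstream_exon_edge"])[-exon_len:],
        )
        di = rec.sequences["downstream_intron"][:intron_len]
        di_c = np.asarray(rec.conservation["downstream_intron"])[:intron_len]
        _count_into(down[i], di, di_c)
    return up, down


def rank_pentamers(
    foreground: Sequence[ExonFlankRecord],
    phylop_min: float = PHYLOP_MIN,
    intron_len: int = 200,
    exon_len: int = 50,
) -> pd.DataFrame:
    """Rank pentamers by how well their flank counts predict ΔPSI.

    For each pentamer, fit ΔPSI ~ upstream_count + downstream_count by
    ordinary least squares over the foreground exons and compute the
    adjusted R² (n, p = 2 correction); pentamers whose counts are constant
    get adjusted R² = 0 by convention.  Ranked descending, ties broken
    lexicographically by pentamer.
    """
    records = [r for r in foreground if r.delta_psi is not None]
    if len(records) < 10:
        raise ValueError("need at least 10 foreground exons with defined delta_psi")
    y = np.array([r.delta_psi for r in records], dtype=float)
    up, down = _flank_counts(records, phylop_min, intron_len, exon_len)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))

    adj = np.zeros(len(_PENTAMERS))
    for code in range(len(_PENTAMERS)):
        u = up[:, code]
        d = down[:, code]
        if (u == u[0]).all() and (d == d[0]).all():
            adj[code] = 0.0
            continue
        X = np.column_stack([np.ones(n), u, d])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        adj[code] = 1.0 - (1.0 - r2) * (n - 1) / (n - 2 - 1)
    df = pd.DataFrame({"pentamer": _PENTAMERS, "adj_r2": adj})
    df = df.sort_values(["adj_r2", "pentamer"], ascending=[False, True]).reset_index(
        drop=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# File interfaces

def write_flank_records(
    records: Sequence[ExonFlankRecord],
    fasta_path,
    conservation_path,
) -> None:
    """Write records as FASTA (`exon_id|region|set|delta_psi` headers) plus
    a long conservation TSV (exon_id, region, offset, phylop)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq_records = []
    cons_rows = []
    for rec in records:
        dpsi = "" if rec.delta_psi is None else f"{rec.delta_psi:.6g}"
        for region in REGIONS:
            header = f"{rec.exon_id}|{region}|{rec.set_label}|{dpsi}"
            seq_records.append(
                SeqRecord(Seq(rec.sequences[region]), id=header, description="")
            )
            for offset, value in enumerate(np.asarray(rec.conservation[region])):
                cons_rows.append((rec.exon_id, region, offset, float(value)))
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    pd.DataFrame(
        cons_rows, columns=["exon_id", "region", "offset", "phylop"]
    ).to_csv(conservation_path, sep="\t", index=False)


def read_flank_records(fasta_path, conservation_path) -> list[ExonFlankRecord]:
    """Read records written by :func:`write_flank_records`."""
    from Bio import SeqIO

    cons = pd.read_csv(conservation_path, sep="\t")
    cons_map: dict[tuple[str, str], np.ndarray] = {
        (str(eid), str(region)): grp.sort_values("offset")["phylop"].to_numpy(dtype=float)
        for (eid, region), grp in cons.groupby(["exon_id", "region"])
    }
    seqs: dict[str, dict[str, str]] = {}
    meta: dict[str, tuple[str, float | None]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        exon_id, region, set_label, dpsi = rec.id.split("|")
        seqs.setdefault(exon_id, {})[region] = str(rec.seq)
        meta[exon_id] = (set_label, float(dpsi) if dpsi else None)
    out = []
    for exon_id, regions in seqs.items():
        set_label, dpsi = meta[exon_id]
        out.append(
            ExonFlankRecord(
                exon_id=exon_id,
                set_label=set_label,
                sequences=regions,
                conservation={r: cons_map[(exon_id, r)] for r in regions},
                delta_psi=dpsi,
            )
        )
    return out
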