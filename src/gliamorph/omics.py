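"""Multi-omics integration rules downstream of standard sequencing tools.

This module consumes the *outputs* of peak callers, differential-expression
tools, miRNA target databases and GO enrichment services — it never re-runs
them — and implements the set-level integration logic:

* condition-unique peak identification (a peak present in one condition
  with no overlapping peak in the other);
* 8-category genomic annotation of peaks by midpoint, with strand-aware
  promoter-TSS (−1 kb .. +100 bp) and TTS (−100 bp .. +1 kb) windows;
* top-N capping of peak lists by score;
* consensus miRNA target voting (top 50 per database, ≥2 databases);
* GO-term binning into 10 biological-process subcategories;
* 2- and 3-way Venn region counts.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ANNOTATION_CATEGORIES",
    "DEFAULT_PRIORITY",
    "GO_SUBCATEGORIES",
    "unique_peaks",
    "annotate_peak",
    "annotate_peaks",
    "category_distribution",
    "top_n_by_score",
    "consensus_targets",
    "ConsensusResult",
    "bin_go_terms",
    "venn_overlap",
    "read_bed",
    "write_bed",
]

logger = logging.getLogger(__name__)

#: the eight genomic annotation categories
ANNOTATION_CATEGORIES = (
    "promoter-TSS", "exon", "intron", "5'UTR", "3'UTR", "CpG-Island", "TTS", "others",
)

#: midpoint category priority, promoter-first (HOMER-style); configurable
DEFAULT_PRIORITY = (
    "promoter-TSS", "TTS", "5'UTR", "3'UTR", "CpG-Island", "exon", "intron",
)

#: the ten biological-process subcategories used for GO binning
GO_SUBCATEGORIES = (
    "cell proliferation and differentiation",
    "cellular process",
    "developmental process",
    "immune-related process",
    "macromolecule processing",
    "response to stimulus",
    "signaling",
    "synapse-related function",
    "transport",
    "others",
)

# promoter / TTS window extents, in bp along the direction of transcription
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


@dataclass(frozen=True)
class GenomicInterval:
    """A scored genomic interval (e.g. a ChIP-seq peak), 0-based half-open."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TTS and genomic exon/UTR intervals.

    For a ``+`` strand gene TSS < TTS; for ``−`` the TSS is the high
    coordinate.  Exon and UTR intervals are genomic (strand-agnostic)
    half-open pairs.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss >= self.tts:
            raise ValueError("+ strand gene must have TSS < TTS")
        if self.strand == "-" and self.tss <= self.tts:
            raise ValueError("- strand gene must have TSS > TTS")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tts), max(self.tss, self.tts))

    def signed_offset(self, position: int) -> int:
        """Position relative to the TSS, in the direction of transcription."""
        return position - self.tss if self.strand == "+" else self.tss - position

    def signed_offset_tts(self, position: int) -> int:
        return position - self.tts if self.strand == "+" else self.tts - position


# ---------------------------------------------------------------------------
# unique peaks
# ---------------------------------------------------------------------------

def unique_peaks(
    condition_peaks: list[GenomicInterval],
    reference_peaks: list[GenomicInterval],
    min_overlap_bp: int = 1,
    known_chroms: set[str] | None = None,
) -> list[GenomicInterval]:
    """Peaks of the condition set that overlap NO reference peak.

    A condition peak is *unique* when no reference peak on the same
    chromosome overlaps it by at least ``min_overlap_bp`` base pairs.
    Implemented as a per-chromosome sweep over start-sorted reference
    intervals; the output preserves the input order of ``condition_peaks``.

    If ``known_chroms`` is given, peaks on other chromosomes are excluded
    with a warning rather than silently annotated.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in reference_peaks}:
        ivs = sorted((p.start, p.end) for p in reference_peaks if p.chrom == chrom)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        # running max of ends bounds the leftward sweep from a binary search
        maxend = np.maximum.accumulate(ends)
        ref_by_chrom[chrom] = (starts, ends, maxend)

    out: list[GenomicInterval] = []
    skipped = 0
    for peak in condition_peaks:
        if known_chroms is not None and peak.chrom not in known_chroms:
            skipped += 1
            continue
        hit = False
        if peak.chrom in ref_by_chrom:
            starts, ends, maxend = ref_by_chrom[peak.chrom]
            # candidates start early enough that an overlap of min_overlap_bp
            # is still geometrically possible
            hi = int(np.searchsorted(starts, peak.end - min_overlap_bp, side="right"))
            for i in range(hi - 1, -1, -1):
                if maxend[i] - peak.start < min_overlap_bp:
                    break  # no interval at or before i reaches far enough right
                ov = min(int(ends[i]), peak.end) - max(int(starts[i]), peak.start)
                if ov >= min_overlap_bp:
                    hit = True
                    break
        if not hit:
            out.append(peak)
    if skipped:
        msg = f"unique_peaks: excluded {skipped} peaks on chromosomes outside the genome"
        warnings.warn(msg)
        logger.warning(msg)
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _midpoint_category(
    mid: int,
    chrom: str,
    genes: list[GeneModel],
    cpg: list[GenomicInterval] | None,
) -> dict[str, bool]:
    """Which categories the midpoint falls in (before priority resolution)."""
    inside: dict[str, bool] = {c: False for c in ANNOTATION_CATEGORIES}
    for g in genes:
        if g.chrom != chrom:
            continue
        rel = g.signed_offset(mid)
        if -PROMOTER_UPSTREAM <= rel <= PROMOTER_DOWNSTREAM:
            inside["promoter-TSS"] = True
        rel_t = g.signed_offset_tts(mid)
        if -TTS_UPSTREAM <= rel_t <= TTS_DOWNSTREAM:
            inside["TTS"] = True
        for lo, hi in g.utr5:
            if lo <= mid < hi:
                inside["5'UTR"] = True
        for lo, hi in g.utr3:
            if lo <= mid < hi:
                inside["3'UTR"] = True
        in_exon = any(lo <= mid < hi for lo, hi in g.exons)
        if in_exon:
            inside["exon"] = True
        lo, hi = g.span
        if lo <= mid < hi and not in_exon:
            inside["intron"] = True
    if cpg:
        for island in cpg:
            if island.chrom == chrom and island.start <= mid < island.end:
                inside["CpG-Island"] = True
                break
    return inside


def annotate_peak(
    peak: GenomicInterval,
    genes: list[GeneModel],
    cpg_islands: list[GenomicInterval] | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    known_chroms: set[str] | None = None,
) -> str:
    """Assign the peak midpoint to exactly one of the eight categories.

    Categories are tested in ``priority`` order (promoter-first by
    default); a midpoint matching none of them is ``"others"``.  The
    promoter window is −1 kb .. +100 bp around the TSS and the TTS window
    −100 bp .. +1 kb around the TTS, both measured along the direction of
    transcription.  Without a CpG-island track that category is simply
    never assigned and peaks fall through the chain.
    """
    if known_chroms is not None and peak.chrom not in known_chroms:
        raise ValueError(f"unknown chromosome {peak.chrom!r}")
    inside = _midpoint_category(peak.midpoint, peak.chrom, genes, cpg_islands)
    for cat in priority:
        if inside.get(cat):
            return cat
    return "others"


def annotate_peaks(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    cpg_islands: list[GenomicInterval] | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    known_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Annotate many peaks; returns a frame with one row per peak."""
    rows = []
    for i, p in enumerate(peaks):
        cat = annotate_peak(p, genes, cpg_islands, priority, known_chroms)
        rows.append({
            "name": p.name or f"peak_{i}",
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "score": p.score, "category": cat,
        })
    return pd.DataFrame(rows)


def category_distribution(categories) -> pd.Series:
    """Percentage of peaks per annotation category (sums to 100)."""
    if isinstance(categories, pd.DataFrame):
        categories = categories["category"]
    cats = pd.Series(list(categories), dtype=object)
    if len(cats) == 0:
        raise ValueError("no peaks to summarize")
    counts = cats.value_counts()
    counts = counts.reindex(
        [c for c in ANNOTATION_CATEGORIES if c in counts.index] +
        [c for c in counts.index if c not in ANNOTATION_CATEGORIES]
    )
    return counts / counts.sum() * 100.0


def top_n_by_score(peaks: list[GenomicInterval], n: int = 3000) -> list[GenomicInterval]:
    """The ``n`` highest-scoring peaks; ties broken by (chrom, start).

    Mirrors the cap applied when feeding ranked peak lists to enrichment
    services with an input limit.  If there are at most ``n`` peaks the
    input is returned unchanged (as a copy).
    """
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    return ranked[: n] if n < len(ranked) else list(peaks)


# ---------------------------------------------------------------------------
# miRNA target consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Vote table of target-gene predictions across databases."""

    votes: dict[str, frozenset]          # every gene -> supporting databases
    selected: dict[str, frozenset]       # genes with >= min_votes support
    min_votes: int = 2

    @property
    def genes(self) -> set:
        return set(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "n_votes": len(dbs), "databases": ",".join(sorted(dbs)),
             "selected": g in self.selected}
            for g, dbs in sorted(self.votes.items())
        ]
        return pd.DataFrame(rows)


def consensus_targets(
    lists: dict[str, list[str]],
    top_n: int = 50,
    min_votes: int = 2,
) -> ConsensusResult:
    """Select genes supported by at least ``min_votes`` databases.

    Each database contributes its ``top_n`` ranked genes.  Duplicates
    within one list are deduplicated keeping the best rank (logged), then
    genes present in ``min_votes`` or more truncated lists are selected.
    """
    if len(lists) < 2:
        raise ValueError("consensus requires at least two databases")
    votes: dict[str, set] = {}
    for db, ranked in lists.items():
        seen: list[str] = []
        dup = 0
        for gene in ranked:
            if gene in seen:
                dup += 1
                continue
            seen.append(gene)
        if dup:
            logger.info("consensus_targets: %d duplicate entries dropped from %s", dup, db)
        for gene in seen[: top_n]:
            votes.setdefault(gene, set()).add(db)
    frozen = {g: frozenset(dbs) for g, dbs in votes.items()}
    selected = {g: dbs for g, dbs in frozen.items() if len(dbs) >= min_votes}
    return ConsensusResult(votes=frozen, selected=selected, min_votes=min_votes)


# ---------------------------------------------------------------------------
# GO binning and Venn overlaps
# ---------------------------------------------------------------------------

def bin_go_terms(terms: pd.DataFrame, mapping: dict[str, str]) -> pd.Series:
    """Percentage composition of GO terms over the 10 subcategories.

    ``terms`` needs a ``term_id`` column (a ``label`` and Benjamini-adjusted
    ``adj_p`` column are carried through if present but unused here);
    ``mapping`` maps term ids to subcategory names.  Unmapped terms fall
    into ``"others"`` and are logged.  Percentages sum to 100.
    """
    if len(terms) == 0:
        raise ValueError("no GO terms to bin")
    ids = terms["term_id"] if isinstance(terms, pd.DataFrame) else pd.Series(list(terms))
    assigned, unmapped = [], 0
    for t in ids:
        sub = mapping.get(t)
        if sub is None:
            unmapped += 1
            sub = "others"
        elif sub not in GO_SUBCATEGORIES:
            raise ValueError(f"unknown subcategory {sub!r} for term {t!r}")
        assigned.append(sub)
    if unmapped:
        logger.info("bin_go_terms: %d unmapped terms assigned to 'others'", unmapped)
    counts = pd.Series(assigned).value_counts()
    counts = counts.reindex([c for c in GO_SUBCATEGORIES if c in counts.index])
    return counts / counts.sum() * 100.0


def venn_overlap(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a 2- or 3-set Venn diagram.

    Keys are sorted label tuples; the value for ``("A", "B")`` counts
    elements in A∩B but in no other set, so all regions sum to ``|union|``.
    """
    labels = sorted(sets)
    if len(labels) not in (2, 3):
        raise ValueError("venn_overlap supports exactly 2 or 3 sets")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(set(sets[l]) for l in combo))
            outside = set.union(*(set(sets[l]) for l in labels if l not in combo), set())
            regions[combo] = len(inside - outside)
    return regions


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (chrom, start, end[, name, score]) into intervals."""
    peaks = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else None
        score = float(row[4]) if len(row) > 4 else 0.0
        peaks.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]),
                                     score=score, name=name))
    return peaks


def write_bed(peaks: list[GenomicInterval], path) -> None:
    rows = [
        (p.chrom, p.start, p.end, p.name or f"peak_{i}", p.score)
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
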