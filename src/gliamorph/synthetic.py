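"""Seeded synthetic inputs for every stage of the pipeline.

Real inputs to the analysis are microscopy crops of Iba1-labelled
microglia, peak-caller output over a reference genome, ranked target-gene
lists from miRNA databases, and grouped per-animal measurement tables.
None of these is needed to exercise or validate the machinery: this module
generates all four with controlled ground truth and per-object seeded
randomness, so every downstream operation can be tested against planted
structure.

The silhouette generator draws a filled soma disk plus recursively
branching processes as integer Bresenham strokes, so images are
reproducible bit-for-bit for a fixed ``(params, seed)`` on any platform.
Two frozen presets bracket the biology:

* ``RAMIFIED_PRESET`` — surveilling microglia: small soma, many long,
  branching, tortuous processes (high complexity, low circularity);
* ``AMEBOID_PRESET`` — activated microglia: enlarged soma, few short
  stubby processes (compact, near-circular).

The presets are calibrated to reproduce the *direction* of every reported
group contrast (activated cells: lower fractal dimension, roughness,
perimeter and hull size; higher density and circularity), not particular
magnitudes — per-class population means are not published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import BinaryCellPair, outline_of
from .omics import GeneModel, GenomicInterval

__all__ = [
    "MorphologyParams",
    "SyntheticCellLabel",
    "RAMIFIED_PRESET",
    "AMEBOID_PRESET",
    "generate_cell",
    "generate_cell_bank",
    "degrade_to_grayscale",
    "ToyGenome",
    "make_toy_genome",
    "generate_peak_experiment",
    "generate_annotated_peaks",
    "generate_target_lists",
    "generate_grouped_measurements",
]


# ---------------------------------------------------------------------------
# cell silhouettes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Geometry of a synthetic microglial silhouette.

    All lengths are in pixels; ``tortuosity`` is the half-width (radians)
    of the uniform angular jitter applied at every growth step.
    ``branch_probability`` is the chance that a process bifurcates at the
    end of a segment.  Branches leaving the frame are clipped.
    """

    soma_radius_px: float
    n_primary_processes: int
    mean_segment_length_px: float
    branch_probability: float
    max_branch_depth: int
    tortuosity: float
    frame_size_px: int = 340
    stroke_width_px: int = 2

    def __post_init__(self):
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.n_primary_processes < 0 or self.max_branch_depth < 0:
            raise ValueError("counts must be >= 0")
        if self.mean_segment_length_px <= 0 or self.frame_size_px <= 0:
            raise ValueError("lengths must be positive")
        if not 1 <= self.stroke_width_px <= 3:
            raise ValueError("stroke width must be 1-3 px")


@dataclass(frozen=True)
class SyntheticCellLabel:
    """Ground truth for one generated cell; (cell_id, seed) fixes the image."""

    cell_id: str
    class_label: str  # "ramified" | "ameboid"
    seed: int


RAMIFIED_PRESET = MorphologyParams(
    soma_radius_px=10, n_primary_processes=6, mean_segment_length_px=28,
    branch_probability=0.7, max_branch_depth=4, tortuosity=0.35,
)

AMEBOID_PRESET = MorphologyParams(
    soma_radius_px=16, n_primary_processes=2, mean_segment_length_px=9,
    branch_probability=0.1, max_branch_depth=1, tortuosity=0.35,
)


def _disk_mask(canvas: np.ndarray, cy: int, cx: int, r: float) -> None:
    """Fill an integer-rasterized disk in place (midpoint rule: d^2 <= r^2)."""
    r_int = int(math.ceil(r))
    y0, y1 = max(cy - r_int, 0), min(cy + r_int + 1, canvas.shape[0])
    x0, x1 = max(cx - r_int, 0), min(cx + r_int + 1, canvas.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _bresenham(y0: int, x0: int, y1: int, x1: int):
    """Integer line pixels from (y0,x0) to (y1,x1), endpoints inclusive."""
    dy, dx = abs(y1 - y0), abs(x1 - x0)
    sy = 1 if y1 >= y0 else -1
    sx = 1 if x1 >= x0 else -1
    err = dx - dy
    y, x = y0, x0
    while True:
        yield y, x
        if y == y1 and x == x1:
            return
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy


def _stroke(canvas: np.ndarray, y0, x0, y1, x1, width: int) -> None:
    """Draw a clipped integer line of the given width (1-3 px)."""
    h, w = canvas.shape
    offsets = {1: [(0, 0)],
               2: [(0, 0), (0, 1), (1, 0), (1, 1)],
               3: [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]}[width]
    for y, x in _bresenham(y0, x0, y1, x1):
        for dy, dx in offsets:
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                canvas[yy, xx] = True


def generate_cell(
    params: MorphologyParams, seed: int, cell_id: str = "cell"
) -> BinaryCellPair:
    """Rasterize one cell silhouette; deterministic for fixed (params, seed).

    The filled image is a soma disk at the frame centre plus recursively
    branching strokes rooted on the soma rim; the outlined image is the
    4-adjacent boundary of the fill.  The result is always a single
    8-connected component.

    Raises ``ValueError("degenerate soma")`` for a non-positive soma radius.
    """
    if params.soma_radius_px <= 0:
        raise ValueError("degenerate soma")
    rng = np.random.default_rng(seed)
    F = params.frame_size_px
    canvas = np.zeros((F, F), dtype=bool)
    cy = cx = F // 2
    _disk_mask(canvas, cy, cx, params.soma_radius_px)

    def grow(y: float, x: float, angle: float, depth: int) -> None:
        if depth <= 0:
            return
        jitter = rng.uniform(-params.tortuosity, params.tortuosity)
        a = angle + jitter
        length = params.mean_segment_length_px * rng.uniform(0.7, 1.3)
        y1 = y + length * math.sin(a)
        x1 = x + length * math.cos(a)
        _stroke(canvas, int(round(y)), int(round(x)), int(round(y1)),
                int(round(x1)), params.stroke_width_px)
        branch = rng.uniform() < params.branch_probability
        if branch:
            split = rng.uniform(0.3, 0.7)
            grow(y1, x1, a - split, depth - 1)
            grow(y1, x1, a + split, depth - 1)
        else:
            grow(y1, x1, a, depth - 1)

    for k in range(params.n_primary_processes):
        base = 2 * math.pi * k / max(params.n_primary_processes, 1)
        a = base + rng.uniform(-params.tortuosity, params.tortuosity)
        # root on the rim (one px inside) so strokes stay 8-connected to the soma
        ry = cy + (params.soma_radius_px - 1) * math.sin(a)
        rx = cx + (params.soma_radius_px - 1) * math.cos(a)
        grow(ry, rx, a, params.max_branch_depth)

    # clipping can in principle strand pixels; keep the component holding the soma
    from skimage.measure import label as _label
    labels = _label(canvas, connectivity=2)
    canvas = labels == labels[cy, cx]
    return BinaryCellPair(filled=canvas, outlined=outline_of(canvas),
                          cell_id=cell_id, frame=F)


def _child_seed(master_seed: int, index: int) -> int:
    """One RNG stream per object, derived from (master seed, object index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cell_bank(
    n_per_class: int = 50,
    master_seed: int = 0,
    ramified: MorphologyParams = RAMIFIED_PRESET,
    ameboid: MorphologyParams = AMEBOID_PRESET,
) -> tuple[list[BinaryCellPair], list[SyntheticCellLabel]]:
    """A labelled two-class bank of silhouettes (ramified first)."""
    pairs, labels = [], []
    idx = 0
    for cls, params in (("ramified", ramified), ("ameboid", ameboid)):
        for i in range(n_per_class):
            seed = _child_seed(master_seed, idx)
            cid = f"{cls}_{i:03d}"
            pairs.append(generate_cell(params, seed, cell_id=cid))
            labels.append(SyntheticCellLabel(cell_id=cid, class_label=cls, seed=seed))
            idx += 1
    return pairs, labels


def degrade_to_grayscale(
    pair: BinaryCellPair, seed: int, blur_sigma: float = 0.5, noise_sd: float = 10.0
) -> np.ndarray:
    """Turn a binary silhouette into a noisy grayscale image.

    Foreground at 200, background at 20, Gaussian blur then additive
    Gaussian noise, clipped to [0, 255].  This emulates the *digital* path
    of a fluorescence image (soft edges, sensor noise), not the optics;
    the default edge softness is half a pixel so the thinnest (2 px)
    processes remain recoverable by thresholding.
    """
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    img = np.where(pair.filled, 200.0, 20.0)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255)


# ---------------------------------------------------------------------------
# toy genome and peak experiments
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    """A small annotated genome: chromosome sizes, gene models, CpG islands."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            lo, hi = g.span
            if lo < 0 or hi > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome")

    @property
    def chroms(self) -> set[str]:
        return set(self.chrom_lengths)


# fixed intra-gene layout (offsets along the direction of transcription, bp):
# exons at [0,300), [4000,4500), [9500,10000); 5'UTR [150,300); 3'UTR [9800,10000)
_GENE_LEN = 10_000
_GENE_SPACING = 30_000
_REL_EXONS = ((0, 300), (4000, 4500), (9500, 10000))
_REL_UTR5 = ((150, 300),)
_REL_UTR3 = ((9800, 10000),)


def _rel_to_genomic(tss: int, strand: str, rel: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rel
    if strand == "+":
        return (tss + lo, tss + hi)
    return (tss - hi, tss - lo)


def make_toy_genome(
    n_genes_per_chrom: int = 20,
    chrom_lengths: dict[str, int] | None = None,
    with_cpg: bool = True,
) -> ToyGenome:
    """A deterministic toy genome with alternating-strand genes.

    Genes are 10 kb long, spaced 30 kb apart, with a fixed three-exon
    layout; one intergenic CpG island is placed 6 kb upstream of each
    gene.  The layout guarantees unambiguous category regions for planting
    peaks (see :func:`generate_annotated_peaks`).
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 700_000, "chr2": 700_000}
    genes, islands = [], []
    for ci, (chrom, length) in enumerate(sorted(chrom_lengths.items())):
        for gi in range(n_genes_per_chrom):
            span_start = 20_000 + gi * _GENE_SPACING
            if span_start + _GENE_LEN + 2000 > length:
                raise ValueError("chromosome too short for requested gene count")
            strand = "+" if (gi % 2 == 0) else "-"
            tss = span_start if strand == "+" else span_start + _GENE_LEN
            tts = span_start + _GENE_LEN if strand == "+" else span_start
            exons = tuple(sorted(_rel_to_genomic(tss, strand, r) for r in _REL_EXONS))
            utr5 = tuple(_rel_to_genomic(tss, strand, r) for r in _REL_UTR5)
            utr3 = tuple(_rel_to_genomic(tss, strand, r) for r in _REL_UTR3)
            genes.append(GeneModel(
                gene_id=f"g{ci}_{gi:03d}", chrom=chrom, strand=strand,
                tss=tss, tts=tts, exons=exons, utr5=utr5, utr3=utr3,
            ))
            if with_cpg:
                islands.append(GenomicInterval(
                    chrom, span_start - 6000, span_start - 5400,
                    name=f"cpg_{ci}_{gi:03d}"))
    return ToyGenome(chrom_lengths=chrom_lengths, genes=genes, cpg_islands=islands)


def generate_peak_experiment(
    genome: ToyGenome,
    n_peaks_per_condition: int,
    fraction_shared: float,
    seed: int,
    peak_length: int = 200,
    min_gap: int = 100,
):
    """Two peak sets with a controlled shared fraction and known uniques.

    ``floor(fraction_shared * n)`` peak positions are occupied in both
    conditions (condition B shifted by under half a peak length, so the
    overlap is >= 1 bp); all remaining peaks are placed in disjoint slots
    and are condition-unique by construction.

    Returns ``(peaks_a, peaks_b, truth)`` where ``truth`` maps
    ``"unique_a"``/``"unique_b"`` to the ground-truth peak-name sets.

    Raises ``ValueError`` if the genome cannot host the required number of
    non-overlapping slots at the minimum spacing.
    """
    if not 0.0 <= fraction_shared <= 1.0:
        raise ValueError("fraction_shared must be in [0, 1]")
    n = n_peaks_per_condition
    n_shared = int(math.floor(fraction_shared * n))
    n_unique = n - n_shared
    slots_needed = n_shared + 2 * n_unique

    slot_pitch = peak_length + min_gap
    slots: list[tuple[str, int]] = []
    for chrom, length in sorted(genome.chrom_lengths.items()):
        for start in range(0, length - peak_length, slot_pitch):
            slots.append((chrom, start))
    if slots_needed > len(slots):
        raise ValueError(
            f"genome capacity exceeded: need {slots_needed} slots, have {len(slots)}")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=slots_needed, replace=False)
    shared_slots = [slots[i] for i in chosen[:n_shared]]
    a_slots = [slots[i] for i in chosen[n_shared:n_shared + n_unique]]
    b_slots = [slots[i] for i in chosen[n_shared + n_unique:]]

    def peak(chrom, start, name):
        return GenomicInterval(chrom, start, start + peak_length,
                               score=float(rng.gamma(4.0, 10.0)), name=name)

    peaks_a, peaks_b = [], []
    for i, (chrom, start) in enumerate(shared_slots):
        shift = int(rng.integers(0, peak_length // 2))  # keeps >=1 bp overlap
        peaks_a.append(peak(chrom, start, f"shared_{i}"))
        peaks_b.append(peak(chrom, start + shift, f"shared_{i}"))
    for i, (chrom, start) in enumerate(a_slots):
        peaks_a.append(peak(chrom, start, f"uniqA_{i}"))
    for i, (chrom, start) in enumerate(b_slots):
        peaks_b.append(peak(chrom, start, f"uniqB_{i}"))

    truth = {
        "unique_a": {p.name for p in peaks_a if p.name.startswith("uniqA")},
        "unique_b": {p.name for p in peaks_b if p.name.startswith("uniqB")},
    }
    return peaks_a, peaks_b, truth


# safe planting offsets per category, relative to the TSS along transcription
# (chosen so priority resolution cannot reassign them; see make_toy_genome)
_PLANT_OFFSETS = {
    "promoter-TSS": (-900, -200),
    "5'UTR": (170, 280),
    "exon": (4100, 4400),
    "intron": (5500, 6500),
    "3'UTR": (9815, 9885),
    "TTS": (_GENE_LEN + 200, _GENE_LEN + 900),
}
# "others" peaks go 5-8 kb past the high end of the gene span in *genomic*
# coordinates: intergenic on either strand, clear of every window and island
_OTHERS_OFFSET = (5000, 8000)


def generate_annotated_peaks(
    genome: ToyGenome,
    category_counts: dict[str, int],
    seed: int,
    peak_width: int = 200,
) -> tuple[list[GenomicInterval], list[str]]:
    """Peaks whose midpoint category is known by construction.

    For each requested category, peaks are planted at offsets that the toy
    genome's layout makes unambiguous under the promoter-first priority
    chain.  Returns the peaks plus the parallel ground-truth category list.
    """
    rng = np.random.default_rng(seed)
    peaks, truth = [], []
    genes = genome.genes
    for cat, count in category_counts.items():
        for i in range(count):
            g = genes[int(rng.integers(0, len(genes)))]
            if cat == "CpG-Island":
                if not genome.cpg_islands:
                    raise ValueError("toy genome has no CpG islands")
                isl = genome.cpg_islands[int(rng.integers(0, len(genome.cpg_islands)))]
                mid = int(rng.integers(isl.start + 10, isl.end - 10))
                chrom = isl.chrom
            elif cat == "others":
                mid = g.span[1] + int(rng.integers(*_OTHERS_OFFSET))
                chrom = g.chrom
            else:
                lo, hi = _PLANT_OFFSETS[cat]
                rel = int(rng.integers(lo, hi + 1))
                mid = g.tss + rel if g.strand == "+" else g.tss - rel
                chrom = g.chrom
            start = max(mid - peak_width // 2, 0)
            peaks.append(GenomicInterval(
                chrom, start, start + peak_width,
                score=float(rng.gamma(4.0, 10.0)), name=f"{cat}_{i}"))
            truth.append(cat)
    return peaks, truth


# ---------------------------------------------------------------------------
# target lists and measurement tables
# ---------------------------------------------------------------------------

def generate_target_lists(
    n_databases: int,
    list_length: int,
    planted_consensus_genes: list[str],
    seed: int,
) -> dict[str, list[str]]:
    """Ranked per-database gene lists with planted multi-database genes.

    Each planted gene is inserted into a random subset of >= 2 databases;
    filler genes are unique to one database, so the planted set is exactly
    the >= 2-vote consensus.  List order (rank) is shuffled per database.
    """
    planted = list(planted_consensus_genes)
    if len(planted) > list_length:
        raise ValueError("more planted genes than list slots")
    rng = np.random.default_rng(seed)
    db_names = [f"db{i + 1}" for i in range(n_databases)]
    lists: dict[str, list[str]] = {db: [] for db in db_names}
    for gene in planted:
        k = int(rng.integers(2, n_databases + 1))
        for db_i in rng.choice(n_databases, size=k, replace=False):
            lists[db_names[db_i]].append(gene)
    filler_id = 0
    for db in db_names:
        while len(lists[db]) < list_length:
            lists[db].append(f"FILLER_{db}_{filler_id}")
            filler_id += 1
        perm = rng.permutation(list_length)
        lists[db] = [lists[db][i] for i in perm]
    return lists


def generate_grouped_measurements(
    group_means: list[float],
    group_sds: list[float],
    n_per_group: int,
    n_outliers: int = 0,
    outlier_offset: float = 0.0,
    seed: int = 0,
    group_names: list[str] | None = None,
) -> pd.DataFrame:
    """Gaussian group samples with flagged injected outliers.

    Returns a frame with columns ``group``, ``value``, ``is_outlier``; the
    first ``n_outliers`` draws of each group are displaced by
    ``outlier_offset`` and flagged.
    """
    if len(group_means) != len(group_sds):
        raise ValueError("means and sds must have equal length")
    if any(sd <= 0 for sd in group_sds):
        raise ValueError("standard deviations must be positive")
    if n_outliers > n_per_group:
        raise ValueError("n_outliers exceeds group size")
    if group_names is None:
        group_names = [f"group{i + 1}" for i in range(len(group_means))]
    rng = np.random.default_rng(seed)
    rows = []
    for name, mu, sd in zip(group_names, group_means, group_sds):
        values = rng.normal(mu, sd, size=n_per_group)
        for j in range(n_per_group):
            out = j < n_outliers
            rows.append({
                "group": name,
                "value": values[j] + (outlier_offset if out else 0.0),
                "is_outlier": out,
            })
    return pd.DataFrame(rows)
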