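"""Classify variants against regulatory-annotation tracks.

Each variant is scored per track as ``within`` a feature (position inside a
peak), ``near`` one (nearest edge at most ``near_bp`` away, default 500 bp,
inclusive), or ``none``.  The per-variant summary status takes the best
status across tracks, reproducing the within/near/none funnel used to
shortlist potentially functional variants from ENCODE/Roadmap-style tracks.

Coordinate conventions: variants are 1-based (VCF); intervals are 0-based
half-open (BED).  The conversion happens in exactly one place
(:func:`annotate_variant`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from intervaltree import IntervalTree

KNOWN_TRACKS = ("promoter_histone", "enhancer_histone", "dnase", "faire", "protein_bound")
STATUS_ORDER = {"within": 0, "near": 1, "none": 2}
CELL_NOTATION = {"within": "X", "near": "(X)", "none": "."}


@dataclass
class AnnotationMatrix:
    """Variant x track status grid with values within/near/none."""

    statuses: pd.DataFrame  # index: variant ids, columns: track labels
    near_bp: int = 500

    @property
    def variant_ids(self) -> list[str]:
        return list(self.statuses.index)

    @property
    def tracks(self) -> list[str]:
        return list(self.statuses.columns)

    def summary_status(self) -> pd.Series:
        """Best status per variant across tracks (within > near > none)."""
        def best(row):
            return min(row, key=STATUS_ORDER.__getitem__) if len(row) else "none"

        return self.statuses.apply(best, axis=1)

    def to_table(self) -> pd.DataFrame:
        """Human-readable grid mirroring the X / (X) / . notation, plus a
        machine-readable summary column."""
        table = self.statuses.replace(CELL_NOTATION)
        table["summary"] = self.summary_status()
        return table


def build_trees(intervals: pd.DataFrame) -> dict[str, dict[str, IntervalTree]]:
    """track -> chrom -> IntervalTree from a BED-style frame."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in intervals.itertuples(index=False):
        trees.setdefault(row.track, {}).setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end)
        )
    return trees


def annotate_variant(
    pos: int,
    intervals: IntervalTree | None,
    near_bp: int = 500,
) -> tuple[str, float]:
    """Status and bp distance of one 1-based variant against one track.

    Distance is 0 for ``within``, the gap to the nearest interval edge
    otherwise, and +inf when the track has no intervals on the chromosome.
    """
    if intervals is None or len(intervals) == 0:
        return "none", math.inf
    p0 = pos - 1  # BED is 0-based half-open
    if intervals.overlaps_point(p0):
        return "within", 0.0
    dist = min(
        (iv.begin - p0) if p0 < iv.begin else (p0 - (iv.end - 1))
        for iv in intervals
    )
    return ("near", float(dist)) if dist <= near_bp else ("none", float(dist))


def build_annotation_matrix(
    variants: pd.DataFrame,
    intervals: pd.DataFrame,
    near_bp: int = 500,
    tracks: list[str] | None = None,
) -> AnnotationMatrix:
    """Full variant x track status matrix.

    ``variants`` needs variant/chrom/pos columns; ``intervals`` is BED-style
    chrom/start/end/track.  Intervals sharing a track label are merged
    (union) regardless of cell type.
    """
    trees = build_trees(intervals)
    if tracks is None:
        tracks = sorted(trees) if len(trees) else []
    unknown = set(trees) - set(tracks)
    if unknown:
        raise ValueError(f"unknown track labels {sorted(unknown)}; known: {sorted(tracks)}")
    grid = {}
    for track in tracks:
        per_chrom = trees.get(track, {})
        col = []
        for row in variants.itertuples(index=False):
            status, _ = annotate_variant(int(row.pos), per_chrom.get(str(row.chrom)), near_bp)
            col.append(status)
        grid[track] = col
    statuses = pd.DataFrame(grid, index=list(variants["variant"]))
    return AnnotationMatrix(statuses=statuses, near_bp=near_bp)


def filter_regulatory(matrix: AnnotationMatrix, candidates) -> pd.DataFrame:
    """Retain candidates whose summary status is within or near.

    ``candidates`` is any iterable of variant ids (or a CandidateSet).
    Returns a frame with the status that let each variant through.
    """
    summary = matrix.summary_status()
    ids = list(candidates.variant_ids) if hasattr(candidates, "variant_ids") else list(candidates)
    missing = [v for v in ids if v not in summary.index]
    if missing:
        raise KeyError(f"annotation matrix does not cover candidates: {missing[:5]}")
    rows = [(v, summary[v]) for v in ids if summary[v] in ("within", "near")]
    return pd.DataFrame(rows, columns=["variant", "status"])


def summarize_counts(matrix: AnnotationMatrix) -> dict:
    """Summary-status and per-track/status counts."""
    summary = matrix.summary_status()
    counts = summary.value_counts()
    per_track = {
        track: matrix.statuses[track].value_counts().to_dict() for track in matrix.tracks
    }
    return {
        "n_within": int(counts.get("within", 0)),
        "n_near": int(counts.get("near", 0)),
        "n_none": int(counts.get("none", 0)),
        "n_annotated": int(counts.get("within", 0) + counts.get("near", 0)),
        "per_track": per_track,
    }


def load_reference_annotation_grid() -> AnnotationMatrix:
    """Packaged annotation grid for the 46 shortlisted locus variants.

    Transcribed test fixture (X = within a regulatory site, (X) = close to
    one); it is test/reference data, not pipeline input.
    """
    ref = resources.files("regulocal.data").joinpath("encode_annotation_grid.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="SNP")
    notation_to_status = {"X": "within", "(X)": "near", ".": "none"}
    statuses = df.apply(lambda col: col.map(notation_to_status))
    if statuses.isna().any().any():
        raise ValueError("unrecognised cell notation in packaged annotation table")
    return AnnotationMatrix(statuses=statuses, near_bp=500)
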