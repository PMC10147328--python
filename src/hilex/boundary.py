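"""Introgression boundary detection from dual-reference mapping.

Reads from a hybrid introgression line map well to whichever reference
genome matches the local genotype, so the per-gene quantity

    delta = log2(mean count on refB + 0.1) - log2(mean count on refN + 0.1),

computed over the HIL's samples only, is strongly positive inside the
introgressed (donor-derived) interval and strongly negative outside it.
Introgressed segments are called by a simple run rule on position-sorted
deltas: flag genes with delta above a threshold and report maximal runs of
at least ``min_run`` flagged genes, tolerating short gaps of unflagged
genes inside a run.  Boundary coordinates are the outermost flagged
genes' start/end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, HilexError

__all__ = [
    "BoundarySegment",
    "BoundaryError",
    "mapping_deltas",
    "segment_introgression",
    "merge_counts_by_region",
    "write_segments_bed",
]

#: pseudocount added to mean read counts before the log2 transform
PSEUDOCOUNT = 0.1


class BoundaryError(HilexError):
    pass


@dataclass
class BoundarySegment:
    """An inferred introgressed interval (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    members: list = field(default_factory=list)  # gene IDs, position-sorted

    def __len__(self) -> int:
        return len(self.members)


def mapping_deltas(
    refB_counts: CountMatrix,
    refN_counts: CountMatrix,
    hil_samples,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene dual-reference mapping deltas over the HIL's samples.

    Both matrices must already be keyed by the canonical ortholog ID.
    Returns a DataFrame (gene_id index; chrom, position, delta) sorted by
    chromosome then position.
    """
    hil_samples = list(hil_samples)
    missing = refB_counts.gene_ids.symmetric_difference(refN_counts.gene_ids)
    if len(missing):
        raise BoundaryError(
            f"gene {missing[0]!r} present in only one reference matrix"
        )
    genes = refN_counts.gene_ids
    unannotated = genes.difference(annotation.index)
    if len(unannotated):
        raise BoundaryError(f"gene {unannotated[0]!r} missing from annotation")
    mean_b = refB_counts.counts.loc[genes, hil_samples].mean(axis=1)
    mean_n = refN_counts.counts.loc[genes, hil_samples].mean(axis=1)
    delta = np.log2(mean_b + PSEUDOCOUNT) - np.log2(mean_n + PSEUDOCOUNT)
    out = pd.DataFrame(
        {
            "chrom": annotation.loc[genes, "chrom"],
            "position": annotation.loc[genes, "start"],
            "end": annotation.loc[genes, "end"],
            "delta": delta,
        }
    )
    return out.sort_values(["chrom", "position"], kind="mergesort")


def segment_introgression(
    deltas: pd.DataFrame,
    threshold: float = 1.0,
    min_run: int = 5,
    max_gap: int = 2,
) -> list:
    """Call introgressed segments from position-sorted mapping deltas.

    Genes with delta > *threshold* are flagged; a segment is a maximal
    run of flagged genes on one chromosome containing at least *min_run*
    flagged genes, where at most *max_gap* consecutive unflagged genes
    are tolerated inside the run.  Gap genes inside the run are kept as
    members (they lie within the physical interval); the segment's
    coordinates come from the outermost flagged genes.
    """
    segments = []
    for chrom, sub in deltas.groupby("chrom", sort=False):
        pos = sub["position"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise BoundaryError(f"deltas on {chrom!r} are not position-sorted")
        flagged = (sub["delta"] > threshold).to_numpy()
        ids = sub.index.to_numpy()
        i = 0
        n = len(sub)
        while i < n:
            if not flagged[i]:
                i += 1
                continue
            # extend the run: last flagged index reachable with gaps <= max_gap
            last = i
            j = i + 1
            gap = 0
            while j < n and gap <= max_gap:
                if flagged[j]:
                    last = j
                    gap = 0
                else:
                    gap += 1
                j += 1
            n_flagged = int(flagged[i : last + 1].sum())
            if n_flagged >= min_run:
                segments.append(
                    BoundarySegment(
                        chrom=str(chrom),
                        start=int(sub["position"].iloc[i]),
                        end=int(sub["end"].iloc[last]),
                        left_gene=str(ids[i]),
                        right_gene=str(ids[last]),
                        members=list(ids[i : last + 1]),
                    )
                )
            i = last + 1
    return segments


def merge_counts_by_region(
    refB_counts: CountMatrix, refN_counts: CountMatrix, segments
) -> CountMatrix:
    """Merge the dual-reference matrices along the inferred segments.

    Genes inside any segment take their refB counts (they are
    donor-derived and quantified against the donor reference); all other
    genes take refN counts.  Output is tagged ``"merged"``.
    """
    by_chrom: dict = {}
    for seg in segments:
        for other in by_chrom.get(seg.chrom, []):
            if seg.start <= other.end and other.start <= seg.end:
                raise BoundaryError(
                    f"overlapping segments on {seg.chrom}: "
                    f"[{other.start},{other.end}] and [{seg.start},{seg.end}]"
                )
        by_chrom.setdefault(seg.chrom, []).append(seg)
    inside = pd.Index([g for seg in segments for g in seg.members])
    merged = refN_counts.counts.copy()
    inside = inside.intersection(merged.index)
    merged.loc[inside] = refB_counts.counts.loc[inside]
    return CountMatrix(merged, "merged")


def write_segments_bed(segments, path) -> None:
    """Write segments as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t"
                f"{seg.left_gene}..{seg.right_gene}\t{len(seg)}\t.\n"
            )
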