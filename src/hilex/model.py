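"""Model/Results interface tying the pipeline stages together.

:class:`HilExpressionModel` is built from the dual-reference count
matrices plus experiment metadata; ``fit()`` runs ortholog restriction,
introgression-boundary detection, reference merging, detectability
filtering, the NB contrasts, the classification tables and the cross-HIL
statistics, and returns a :class:`HilExpressionResults` carrying every
intermediate table and a ``summary()`` report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import boundary as _boundary
from . import classify as _classify
from . import de as _de
from . import io as _io
from . import stats as _stats

__all__ = ["HilExpressionModel", "HilExpressionResults"]

log = logging.getLogger("hilex")


@dataclass
class HilExpressionResults:
    """Fitted pipeline results for one two-parent / multi-HIL experiment."""

    model: "HilExpressionModel"
    deltas: dict           # HIL label -> mapping-delta table
    segments: dict         # HIL label -> list of BoundarySegment
    merged_counts: dict    # HIL label -> merged, detectability-filtered CountMatrix
    triplets: dict         # HIL label -> ContrastTriplet
    calls: dict            # HIL label -> per-gene classification table
    report: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable cross-HIL summary."""
        return _stats.format_report(self.report)

    def introgressed_genes(self, label: str) -> set:
        return set(g for seg in self.segments[label] for g in seg.members)

    def to_dir(self, outdir) -> None:
        """Write all per-gene tables, segments and the JSON report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label in self.calls:
            self.deltas[label].to_csv(
                outdir / f"deltas_{label}.tsv", sep="\t", index_label="gene_id"
            )
            _boundary.write_segments_bed(
                self.segments[label], outdir / f"segments_{label}.bed"
            )
            trip = self.triplets[label]
            for name, frame in (("BvN", trip.bvn), ("HvN", trip.hvn), ("HvB", trip.hvb)):
                _de.write_contrast(frame, outdir / f"contrast_{label}_{name}.tsv")
            calls = self.calls[label].copy()
            ann = self.model.annotation
            calls.insert(0, "chrom", ann.loc[calls.index, "chrom"])
            calls.insert(1, "chrom_class", ann.loc[calls.index, "chrom_class"])
            calls.to_csv(outdir / f"calls_{label}.tsv", sep="\t", index_label="gene_id")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "report.txt", "w") as fh:
            fh.write(self.summary())


class HilExpressionModel:
    """Expression-inheritance / regulatory-divergence model for HIL RNA-seq.

    Parameters
    ----------
    refB_counts, refN_counts
        Count matrices of the same libraries quantified against the donor
        (B) and background (N) reference genomes.  Gene IDs may be
        reference-specific if an ortholog map is supplied.
    samples
        Sample sheet (index sample_id; columns group, replicate) with the
        parental groups ``species_B``/``species_N`` plus one label per HIL.
    annotation
        Gene coordinates keyed by canonical gene ID (columns chrom,
        start, end, strand, chrom_class).
    orthologs
        Optional 1:1 ortholog map; when given, both matrices are
        restricted to it and re-keyed to the canonical (refN) IDs.
    padj_threshold
        BH-adjusted significance level shared by all decision tables.
    delta_threshold, min_run, max_gap
        Introgression segmentation rule (see :mod:`hilex.boundary`).
    min_mean
        Detectable-expression filter: minimum mean raw count.
    """

    def __init__(
        self,
        refB_counts: _io.CountMatrix,
        refN_counts: _io.CountMatrix,
        samples: pd.DataFrame,
        annotation: pd.DataFrame,
        orthologs: _io.OrthologMap | None = None,
        *,
        padj_threshold: float = 0.05,
        delta_threshold: float = 1.0,
        min_run: int = 5,
        max_gap: int = 2,
        min_mean: float = 1.0,
        transgressive_requires_parental_difference: bool = False,
    ) -> None:
        self.refB_counts = refB_counts
        self.refN_counts = refN_counts
        self.samples = samples
        self.annotation = annotation
        self.orthologs = orthologs
        self.padj_threshold = padj_threshold
        self.delta_threshold = delta_threshold
        self.min_run = min_run
        self.max_gap = max_gap
        self.min_mean = min_mean
        self.transgressive_requires_parental_difference = (
            transgressive_requires_parental_difference
        )

    # ---------------------------------------------------------------- ctors
    @classmethod
    def from_paths(
        cls,
        counts_refB,
        counts_refN,
        annotation,
        orthologs,
        samples,
        x_chroms=("X", "chrX", "ChrX"),
        **kwargs,
    ) -> "HilExpressionModel":
        return cls(
            _io.read_counts(counts_refB, "refB"),
            _io.read_counts(counts_refN, "refN"),
            _io.read_sample_sheet(samples),
            _io.read_annotation(annotation, frozenset(x_chroms)),
            _io.read_orthologs(orthologs),
            **kwargs,
        )

    @classmethod
    def from_fixture_dir(cls, fixture_dir, **kwargs) -> "HilExpressionModel":
        """Build from a directory written by :func:`hilex.simulate.write_fixture`."""
        d = Path(fixture_dir)
        return cls.from_paths(
            d / "counts_refB.tsv",
            d / "counts_refN.tsv",
            d / "annotation.gff3",
            d / "orthologs.tsv",
            d / "samples.csv",
            **kwargs,
        )

    # ------------------------------------------------------------------ fit
    def fit(self) -> HilExpressionResults:
        ref_b, ref_n = self.refB_counts, self.refN_counts
        if self.orthologs is not None:
            ref_b = _io.restrict_to_orthologs(ref_b, self.orthologs)
            ref_n = _io.restrict_to_orthologs(ref_n, self.orthologs)
            log.info(
                "orthologs: %d -> %d (refB), %d -> %d (refN)",
                self.refB_counts.shape[0], ref_b.shape[0],
                self.refN_counts.shape[0], ref_n.shape[0],
            )
        if not ref_b.gene_ids.equals(ref_n.gene_ids):
            common = ref_b.gene_ids.intersection(ref_n.gene_ids)
            ref_b = _io.CountMatrix(ref_b.counts.loc[common], "refB")
            ref_n = _io.CountMatrix(ref_n.counts.loc[common], "refN")

        labels = _io.hil_groups(self.samples)
        deltas, segments, merged, triplets, calls = {}, {}, {}, {}, {}
        for label in labels:
            hil_samples = _io.samples_in_group(self.samples, label)
            dl = _boundary.mapping_deltas(ref_b, ref_n, hil_samples, self.annotation)
            segs = _boundary.segment_introgression(
                dl, self.delta_threshold, self.min_run, self.max_gap
            )
            log.info("%s: %d segment(s) from %d deltas", label, len(segs), len(dl))
            m = _boundary.merge_counts_by_region(ref_b, ref_n, segs)
            # restrict to this HIL's groups before filtering/normalising
            use = [
                s
                for s, row in self.samples.iterrows()
                if row["group"] in (_io.PARENT_B, _io.PARENT_N, label)
            ]
            m = m.subset_samples(use)
            n_before = m.shape[0]
            m = _io.filter_detectable(m, self.min_mean)
            log.info("%s: detectability filter %d -> %d genes", label, n_before, m.shape[0])
            trip = _de.build_triplet(m, self.samples.loc[use], label)
            cl = _classify.classify_all(
                trip,
                self.padj_threshold,
                self.transgressive_requires_parental_difference,
            )
            deltas[label], segments[label] = dl, segs
            merged[label], triplets[label], calls[label] = m, trip, cl

        seg_members = {
            h: [g for seg in segments[h] for g in seg.members] for h in labels
        }
        report = _stats.summary_report(
            calls, self.annotation, segments, self.padj_threshold
        )
        report["stages"] = {
            h: {
                "n_input_genes": int(ref_n.shape[0]),
                "n_detectable": int(merged[h].shape[0]),
                "n_introgressed": len(seg_members[h]),
            }
            for h in labels
        }
        return HilExpressionResults(
            model=self,
            deltas=deltas,
            segments=segments,
            merged_counts=merged,
            triplets=triplets,
            calls=calls,
            report=report,
        )
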