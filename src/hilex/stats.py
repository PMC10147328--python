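"""Cross-HIL and chromosomal summary statistics.

Overlap of differentially expressed gene (DEG) sets between the two HILs
(Jaccard index plus a one-sided hypergeometric enrichment p, the usual
"Fisher's exact test P_overlap"), autosome-vs-X enrichment of up/down
DEGs (two-sided Fisher), category-concordance matrices for genes DE in
both HILs, and the per-category tallies behind the headline percentages.

Reporting conventions: percentages are rounded to the nearest integer and
Jaccard indices to one decimal, both round-half-up.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import HilexError

__all__ = [
    "OverlapStats",
    "EnrichmentTest",
    "ConcordanceMatrix",
    "jaccard",
    "round_half_up",
    "overlap_test",
    "chrom_enrichment",
    "concordance",
    "category_tally",
    "summary_report",
]


class StatsError(HilexError):
    pass


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.35 -> 0.4 at one digit), as in the report."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def jaccard(n_overlap: int, n_a: int, n_b: int) -> float:
    """Jaccard index |A∩B| / |A∪B| from set sizes."""
    if n_overlap > min(n_a, n_b):
        raise StatsError("overlap exceeds a set size")
    union = n_a + n_b - n_overlap
    if union == 0:
        raise StatsError("Jaccard undefined for two empty sets")
    return n_overlap / union


@dataclass
class OverlapStats:
    n_A: int
    n_B: int
    n_overlap: int
    n_universe: int
    jaccard: float
    p_overlap: float


def overlap_test(n_overlap: int, n_a: int, n_b: int, n_universe: int) -> OverlapStats:
    """Hypergeometric upper-tail test of set overlap.

    P(X >= n_overlap) for X ~ Hypergeom(N=n_universe, K=n_a, n=n_b) —
    the one-sided Fisher enrichment p on the corresponding 2x2 table.
    """
    if n_a > n_universe or n_b > n_universe:
        raise StatsError("set size exceeds universe")
    if n_overlap > min(n_a, n_b):
        raise StatsError("overlap exceeds a set size")
    if n_overlap < max(0, n_a + n_b - n_universe):
        raise StatsError("overlap inconsistent with universe size")
    p = float(sps.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
    return OverlapStats(
        n_A=n_a,
        n_B=n_b,
        n_overlap=n_overlap,
        n_universe=n_universe,
        jaccard=jaccard(n_overlap, n_a, n_b) if (n_a + n_b) else 0.0,
        p_overlap=min(p, 1.0),
    )


@dataclass
class EnrichmentTest:
    table: tuple  # ((a, b), (c, d)) rows: in-direction / not; cols: autosome / X
    odds_ratio: float
    p: float


def chrom_enrichment(
    calls: pd.DataFrame, annotation: pd.DataFrame, direction: str, exclude=()
) -> EnrichmentTest:
    """Autosome-vs-X Fisher test for up- or down-regulated DEGs.

    Builds the 2x2 table (direction vs not) x (autosome vs X) over the
    classified genes, excluding *exclude* (typically introgressed genes,
    per the shared-genome convention), and runs a two-sided Fisher exact
    test.  The odds ratio gets a Haldane 0.5 correction only when a zero
    cell occurs.
    """
    if direction not in ("up", "down"):
        raise StatsError(f"direction must be 'up' or 'down', got {direction!r}")
    keep = calls.index.difference(pd.Index(exclude))
    calls = calls.loc[keep]
    chrom_class = annotation.loc[calls.index, "chrom_class"]
    is_dir = calls["direction"] == direction
    is_auto = chrom_class == "autosome"
    a = int((is_dir & is_auto).sum())
    b = int((is_dir & ~is_auto).sum())
    c = int((~is_dir & is_auto).sum())
    d = int((~is_dir & ~is_auto).sum())
    if (a + c) == 0 or (b + d) == 0:
        raise StatsError("empty chromosome stratum")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        orx = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orx = (a * d) / (b * c)
    return EnrichmentTest(table=((a, b), (c, d)), odds_ratio=float(orx), p=float(p))


@dataclass
class ConcordanceMatrix:
    matrix: pd.DataFrame  # category x category counts (HIL1 rows, HIL2 columns)
    diagonal_fraction: float
    n_shared: int


def concordance(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    which: str = "inheritance",
    threshold: float = 0.05,
    exclude=(),
) -> ConcordanceMatrix:
    """Category agreement for genes differentially expressed in both HILs.

    Restricts to genes with HvN padj below *threshold* in both call
    tables (minus *exclude*), cross-tabulates the chosen category column
    and reports the diagonal fraction — the share of shared DEGs assigned
    the identical category in both lines.
    """
    if which not in ("inheritance", "regulatory"):
        raise StatsError(f"unknown category column {which!r}")
    shared = calls_a.index.intersection(calls_b.index).difference(pd.Index(exclude))
    de_both = shared[
        (calls_a.loc[shared, "padj_HvN"] < threshold)
        & (calls_b.loc[shared, "padj_HvN"] < threshold)
    ]
    if len(de_both) == 0:
        raise StatsError("no gene is differentially expressed in both HILs")
    cats = sorted(
        set(calls_a.loc[de_both, which]).union(calls_b.loc[de_both, which])
    )
    matrix = pd.crosstab(
        calls_a.loc[de_both, which], calls_b.loc[de_both, which]
    ).reindex(index=cats, columns=cats, fill_value=0)
    diag = float(np.trace(matrix.to_numpy()))
    return ConcordanceMatrix(
        matrix=matrix,
        diagonal_fraction=diag / len(de_both),
        n_shared=int(len(de_both)),
    )


def category_tally(calls: pd.DataFrame, direction_filter: str | None = None,
                   which: str = "regulatory") -> pd.Series:
    """Counts per category, optionally restricted to one direction."""
    sub = calls if direction_filter is None else calls[calls["direction"] == direction_filter]
    return sub[which].value_counts().sort_index()


def summary_report(
    calls_by_hil: dict,
    annotation: pd.DataFrame,
    segments_by_hil: dict,
    threshold: float = 0.05,
) -> dict:
    """Assemble the cross-HIL summary (counts, overlaps, concordance).

    All percentages are recomputed from the counts they sit next to;
    Jaccard indices are reported raw and rounded to one decimal.
    """
    labels = list(calls_by_hil)
    report: dict = {"padj_threshold": threshold, "hils": {}}
    members = {
        h: set(g for seg in segments_by_hil.get(h, []) for g in seg.members)
        for h in labels
    }
    de_sets: dict = {}
    for h, calls in calls_by_hil.items():
        shared_calls = calls.loc[calls.index.difference(pd.Index(sorted(members[h])))]
        de = shared_calls.index[shared_calls["padj_HvN"] < threshold]
        down = shared_calls.index[shared_calls["direction"] == "down"]
        up = shared_calls.index[shared_calls["direction"] == "up"]
        de_sets[h] = {"de": set(de), "down": set(down), "up": set(up)}
        n_expr = len(shared_calls)
        enrich = chrom_enrichment(shared_calls, annotation, "down")
        report["hils"][h] = {
            "n_expressed_shared_genome": n_expr,
            "n_deg": int(len(de)),
            "pct_deg": round_half_up(100.0 * len(de) / n_expr),
            "n_down": int(len(down)),
            "n_up": int(len(up)),
            "inheritance_tally": category_tally(shared_calls, which="inheritance").to_dict(),
            "regulatory_tally": category_tally(shared_calls, which="regulatory").to_dict(),
            "down_autosome_enrichment": {
                "table": enrich.table,
                "odds_ratio": enrich.odds_ratio,
                "p": enrich.p,
            },
            "segments": [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "left_gene": s.left_gene,
                    "right_gene": s.right_gene,
                    "n_members": len(s),
                }
                for s in segments_by_hil.get(h, [])
            ],
        }
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        universe = len(
            calls_by_hil[a]
            .index.difference(pd.Index(sorted(members[a])))
            .intersection(
                calls_by_hil[b].index.difference(pd.Index(sorted(members[b])))
            )
        )
        overlaps = {}
        for key in ("down", "up"):
            sa, sb = de_sets[a][key], de_sets[b][key]
            ov = overlap_test(len(sa & sb), len(sa), len(sb), universe)
            overlaps[key] = {
                "n_A": ov.n_A,
                "n_B": ov.n_B,
                "n_overlap": ov.n_overlap,
                "n_universe": ov.n_universe,
                "jaccard": ov.jaccard,
                "jaccard_1dp": round_half_up(ov.jaccard, 1),
                "p_overlap": ov.p_overlap,
            }
        conc = {}
        shared_down = de_sets[a]["down"] & de_sets[b]["down"]
        shared_up = de_sets[a]["up"] & de_sets[b]["up"]
        for which in ("inheritance", "regulatory"):
            try:
                cm = concordance(
                    calls_by_hil[a],
                    calls_by_hil[b],
                    which,
                    threshold,
                    exclude=sorted(members[a] | members[b]),
                )
            except StatsError:  # no shared DEGs (e.g. a null data set)
                conc[which] = {
                    "n_shared_deg": 0,
                    "diagonal_fraction": None,
                    "pct_diagonal": None,
                    "matrix": {},
                }
                continue
            conc[which] = {
                "n_shared_deg": cm.n_shared,
                "diagonal_fraction": cm.diagonal_fraction,
                "pct_diagonal": round_half_up(100.0 * cm.diagonal_fraction),
                "matrix": {r: cm.matrix.loc[r].to_dict() for r in cm.matrix.index},
            }
        # per-direction regulatory tallies among concordant shared DEGs
        calls_a = calls_by_hil[a]
        concordant = [
            g
            for g in sorted(shared_down | shared_up)
            if calls_a.at[g, "regulatory"] == calls_by_hil[b].at[g, "regulatory"]
        ]
        tallies = {}
        for key, pool in (("down", shared_down), ("up", shared_up)):
            genes = [g for g in concordant if g in pool]
            tally = calls_a.loc[genes, "regulatory"].value_counts().to_dict()
            n = len(genes)
            both = tally.get("compensatory", 0) + tally.get("cis_trans_combined", 0)
            tallies[key] = {
                "n": n,
                "tally": tally,
                "pct_cis_and_trans": round_half_up(100.0 * both / n) if n else 0.0,
            }
        report["cross_hil"] = {
            "pair": [a, b],
            "n_universe": universe,
            "overlap": overlaps,
            "concordance": conc,
            "concordant_deg_regulatory_tallies": tallies,
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`summary_report` output."""
    lines = [f"padj threshold: {report['padj_threshold']}"]
    for h, r in report["hils"].items():
        lines += [
            "",
            f"== {h} ==",
            f"expressed genes (shared genome): {r['n_expressed_shared_genome']}",
            f"DEGs: {r['n_deg']} ({r['pct_deg']:.0f}%)  down: {r['n_down']}  up: {r['n_up']}",
            f"down-gene autosome enrichment: OR={r['down_autosome_enrichment']['odds_ratio']:.3g} "
            f"p={r['down_autosome_enrichment']['p']:.3g}",
        ]
        for s in r["segments"]:
            lines.append(
                f"introgression {s['chrom']}:{s['start']}-{s['end']} "
                f"({s['left_gene']}..{s['right_gene']}, {s['n_members']} genes)"
            )
    if "cross_hil" in report:
        x = report["cross_hil"]
        lines += ["", f"== cross-HIL ({' vs '.join(x['pair'])}) =="]
        for key in ("down", "up"):
            o = x["overlap"][key]
            lines.append(
                f"{key}: overlap {o['n_overlap']} of {o['n_A']}/{o['n_B']} "
                f"Jaccard={o['jaccard_1dp']:.1f} p={o['p_overlap']:.3g}"
            )
        for which in ("inheritance", "regulatory"):
            c = x["concordance"][which]
            if c["n_shared_deg"]:
                lines.append(
                    f"{which} concordance: {c['pct_diagonal']:.0f}% "
                    f"of {c['n_shared_deg']} shared DEGs on the diagonal"
                )
            else:
                lines.append(f"{which} concordance: no shared DEGs")
    return "\n".join(lines) + "\n"
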