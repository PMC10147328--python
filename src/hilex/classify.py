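"""Inheritance and regulatory-divergence decision tables.

Each gene's three pairwise contrasts — parent B vs parent N (BvN), HIL vs
parent N (HvN) and HIL vs parent B (HvB) — are reduced to a significance
pattern (padj below threshold?) plus fold-change directions, and two
categorical calls are read off deterministic tables.

Expression-inheritance categories describe where the HIL sits relative to
the two parents: dominant toward either parent, additive (intermediate),
transgressive high/low (outside the parental range), conserved, or
ambiguous.  Regulatory-divergence categories exploit the HIL's genetics
(donor cis elements in a background trans environment): trans-only
divergence makes the HIL track parent B, compensatory cis–trans
divergence misexpresses the HIL while the parents match, combined
cis–trans divergence separates all three, "no effect" leaves the HIL at
the background parent despite parental divergence.  cis-only divergence
is undetectable in this design and never called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import ContrastTriplet
from .io import HilexError

__all__ = [
    "SigPattern",
    "INHERITANCE_CATEGORIES",
    "REGULATORY_CATEGORIES",
    "classify_inheritance",
    "classify_regulatory",
    "direction_call",
    "classify_all",
]

INHERITANCE_CATEGORIES = (
    "cbr_dominant",
    "cni_dominant",
    "additive",
    "transgressive_high",
    "transgressive_low",
    "conserved",
    "ambiguous",
)

REGULATORY_CATEGORIES = (
    "trans_only",
    "compensatory",
    "cis_trans_combined",
    "no_effect",
    "conserved",
    "ambiguous",
)


@dataclass(frozen=True)
class SigPattern:
    """Per-gene significance flags and fold-change signs.

    Fold changes are oriented first-over-second: ``fc_bvn`` = B/N,
    ``fc_hvn`` = H/N, ``fc_hvb`` = H/B, so the two H contrasts are
    "H minus parent" as required by the tables.
    """

    bvn_sig: bool
    hvn_sig: bool
    hvb_sig: bool
    fc_bvn: float = 0.0
    fc_hvn: float = 0.0
    fc_hvb: float = 0.0


class ClassificationError(HilexError):
    pass


def classify_inheritance(
    s: SigPattern, transgressive_requires_parental_difference: bool = False
) -> str:
    """Assign the expression-inheritance category for one gene.

    The table is evaluated in order: conserved; transgressive (HIL
    significantly beyond both parents in the same direction, parental
    status free by default); additive (all three significant, HIL
    strictly between the parents); dominant toward either parent;
    everything else ambiguous.  The table is total.
    """
    if not (s.bvn_sig or s.hvn_sig or s.hvb_sig):
        return "conserved"
    if s.hvn_sig and s.hvb_sig and np.sign(s.fc_hvn) == np.sign(s.fc_hvb) != 0:
        if transgressive_requires_parental_difference and not s.bvn_sig:
            return "ambiguous"
        return "transgressive_high" if s.fc_hvn > 0 else "transgressive_low"
    if (
        s.bvn_sig
        and s.hvn_sig
        and s.hvb_sig
        and np.sign(s.fc_hvn) == -np.sign(s.fc_hvb) != 0
    ):
        return "additive"
    if s.bvn_sig and s.hvb_sig and not s.hvn_sig:
        return "cni_dominant"
    if s.bvn_sig and s.hvn_sig and not s.hvb_sig:
        return "cbr_dominant"
    return "ambiguous"


def classify_regulatory(s: SigPattern) -> str:
    """Assign the regulatory-divergence category for one gene.

    trans-only: parents differ and the HIL tracks parent B (BvN and HvN
    significant, HvB not).  compensatory: parents match but the HIL
    differs from both.  combined cis–trans: all three contrasts
    significant.  no effect: parents differ, HIL stays at parent N.
    conserved: nothing significant.  Anything else is ambiguous.
    """
    sig = (s.bvn_sig, s.hvn_sig, s.hvb_sig)
    if sig == (True, True, False):
        return "trans_only"
    if sig == (False, True, True):
        return "compensatory"
    if sig == (True, True, True):
        return "cis_trans_combined"
    if sig == (True, False, True):
        return "no_effect"
    if sig == (False, False, False):
        return "conserved"
    return "ambiguous"


def direction_call(s: SigPattern) -> str:
    """Direction of the HIL relative to the background parent N."""
    if not s.hvn_sig:
        return "ns"
    if s.fc_hvn > 0:
        return "up"
    if s.fc_hvn < 0:
        return "down"
    raise ClassificationError("significant HvN contrast with log2fc exactly 0")


def classify_all(
    triplet: ContrastTriplet,
    threshold: float = 0.05,
    transgressive_requires_parental_difference: bool = False,
) -> pd.DataFrame:
    """Classify every gene of an aligned contrast triplet.

    Returns a DataFrame indexed by gene_id with columns ``inheritance``,
    ``regulatory``, ``direction``, the HvN log2 fold change and the three
    padj values.  Calls depend only on the padj flags at *threshold* and
    the fold-change signs, so they are invariant to count scale and gene
    order.
    """
    bvn, hvn, hvb = triplet.bvn, triplet.hvn, triplet.hvb
    rows = []
    for gid in triplet.gene_ids:
        s = SigPattern(
            bvn_sig=bool(bvn.at[gid, "padj"] < threshold),
            hvn_sig=bool(hvn.at[gid, "padj"] < threshold),
            hvb_sig=bool(hvb.at[gid, "padj"] < threshold),
            fc_bvn=float(bvn.at[gid, "log2fc"]),
            fc_hvn=float(hvn.at[gid, "log2fc"]),
            fc_hvb=float(hvb.at[gid, "log2fc"]),
        )
        rows.append(
            (
                classify_inheritance(s, transgressive_requires_parental_difference),
                classify_regulatory(s),
                direction_call(s),
            )
        )
    out = pd.DataFrame(
        rows, columns=["inheritance", "regulatory", "direction"], index=triplet.gene_ids
    )
    out["log2fc_HvN"] = hvn["log2fc"]
    out["padj_BvN"] = bvn["padj"]
    out["padj_HvN"] = hvn["padj"]
    out["padj_HvB"] = hvb["padj"]
    return out
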