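"""Synthetic two-species + hybrid-introgression-line RNA-seq generator.

The generator emulates the study design the analysis assumes: two parental
nematode species (a *C. briggsae*-like donor, "B", and a *C. nigoni*-like
background, "N") plus one or more X-linked hybrid introgression lines
(HILs), each sequenced in triplicate, with counts drawn from a negative
binomial with per-gene dispersion.  Each gene is assigned one of five
generative regulatory architectures which fix its expected-count triplet
(mu_B, mu_N, mu_H):

=============  ==========================  =================================
architecture   mean triplet                interpretation
=============  ==========================  =================================
conserved      (mu0, mu0, mu0)             no regulatory divergence
no_effect      (mu0*2^sd, mu0, mu0)        divergence invisible in the HIL
trans_only     (mu0*2^sd, mu0, mu0*2^sd)   shared trans factor drives HIL to B
compensatory   (mu0, mu0, mu0*2^sd)        opposing cis/trans, parents equal
combined       (mu0*2^sd, mu0, mu0*2^ud)   both cis and trans, u*d not in {0, sd}
=============  ==========================  =================================

Genes inside a HIL's introgressed X interval carry the donor's cis
genotype, so their HIL mean is mu_B, and their reads map well only to the
B reference: dual-reference mapping is modelled by scaling the NB mean of
any (gene, sample) pair whose locus genotype does not match the reference
by the mapping-leak factor ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PARENT_B, PARENT_N, CountMatrix, OrthologMap

__all__ = [
    "ARCHITECTURES",
    "SimConfig",
    "make_truth",
    "truth_for_hil",
    "simulate_counts",
    "simulate_experiment",
    "write_fixture",
]

ARCHITECTURES = ("conserved", "no_effect", "trans_only", "compensatory", "combined")

_DEFAULT_FRACTIONS = {
    "conserved": 0.50,
    "no_effect": 0.12,
    "trans_only": 0.12,
    "compensatory": 0.13,
    "combined": 0.13,
}

#: introgressed X intervals as fractions of the X chromosome length,
#: mirroring the study's two lines: one fragment on the right arm and a
#: larger, nonoverlapping one in the middle of the X.
_DEFAULT_INTROGRESSIONS = {"HIL1": (0.62, 0.92), "HIL2": (0.12, 0.52)}

_AUTOSOMES = ("I", "II", "III", "IV", "V")
_GENE_SPACING = 2000  # bp between gene starts in the synthetic layout
_GENE_LENGTH = 1500


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design: ~12,000 1:1 orthologs, ~17% of them
    X-linked, triplicate sampling of each group, and two HILs with
    nonoverlapping X-linked introgressions.  ``effect_size`` is the
    regulatory shift in log2 units; dispersions are drawn log-uniformly
    from ``alpha_range`` (NB variance = mu + alpha*mu^2); ``mapping_leak``
    is the fraction of a locus's reads that still map to the wrong-species
    reference (~21% synonymous-site divergence keeps it small but nonzero).
    """

    n_genes: int = 12000
    fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    effect_size: float = 2.0
    alpha_range: tuple = (0.005, 0.2)
    mu_range: tuple = (20.0, 2000.0)
    n_replicates: int = 3
    lib_factor_range: tuple = (0.7, 1.3)
    x_fraction: float = 0.17
    introgressions: dict = field(
        default_factory=lambda: dict(_DEFAULT_INTROGRESSIONS)
    )
    combined_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    mapping_leak: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"architecture fractions sum to {total}, not 1")
        unknown = set(self.fractions) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown architectures {sorted(unknown)}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0 (use the null via d -> 0+)")
        if not 0.0 <= self.mapping_leak <= 1.0:
            raise ValueError("mapping_leak must be in [0, 1]")

    @property
    def hil_labels(self) -> list:
        return list(self.introgressions)


def _integer_split(n: int, fractions: dict) -> dict:
    """Largest-remainder apportionment of n genes across architectures."""
    raw = {k: n * v for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _gene_layout(cfg: SimConfig) -> pd.DataFrame:
    """Place genes on five autosomes plus the X with uniform spacing."""
    n_x = int(round(cfg.n_genes * cfg.x_fraction))
    n_auto = cfg.n_genes - n_x
    per_auto = [n_auto // len(_AUTOSOMES)] * len(_AUTOSOMES)
    for i in range(n_auto - sum(per_auto)):
        per_auto[i] += 1
    chroms, starts = [], []
    for chrom, k in zip(_AUTOSOMES + ("X",), per_auto + [n_x]):
        chroms.extend([chrom] * k)
        starts.extend(1 + np.arange(k) * _GENE_SPACING)
    gene_ids = [f"gN_{i:06d}" for i in range(cfg.n_genes)]
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=int),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    frame["end"] = frame["start"] + _GENE_LENGTH - 1
    frame["strand"] = np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-")
    return frame


def _introgression_intervals(cfg: SimConfig, layout: pd.DataFrame) -> dict:
    """Resolve per-HIL intervals to (chrom, start_bp, end_bp)."""
    x = layout[layout["chrom"] == "X"]
    span = int(x["end"].max())
    out = {}
    for label, iv in cfg.introgressions.items():
        if len(iv) == 3:  # explicit (chrom, start, end)
            out[label] = (str(iv[0]), int(iv[1]), int(iv[2]))
        else:  # fractional (lo, hi) of the X span
            lo, hi = iv
            out[label] = ("X", int(lo * span) + 1, int(hi * span))
    return out


def make_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-gene ground truth table.

    Returns a DataFrame indexed by gene_id with the architecture, the
    mean triplet (mu_B, mu_N, mu_H), the NB dispersion, genomic placement
    and one ``in_introgression_<label>`` flag per configured HIL.  The
    triplet stored here is the *shared-genome* one; genes inside a HIL's
    introgression express mu_B in that HIL (see :func:`truth_for_hil`).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    layout = _gene_layout(cfg)
    n = cfg.n_genes
    arch_counts = _integer_split(n, cfg.fractions)
    archs = np.concatenate([[a] * k for a, k in arch_counts.items()])
    rng.shuffle(archs)

    lo, hi = cfg.mu_range
    mu0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    a_lo, a_hi = cfg.alpha_range
    if a_lo == a_hi:  # degenerate range, includes the Poisson case alpha=0
        alpha = np.full(n, float(a_lo))
    else:
        alpha = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n))
    sign = rng.choice([-1.0, 1.0], size=n)
    d = cfg.effect_size
    shift = 2.0 ** (sign * d)

    mu_b = np.where(np.isin(archs, ["no_effect", "trans_only", "combined"]), mu0 * shift, mu0)
    mu_n = mu0.copy()
    mu_h = mu0.copy()
    mu_h[archs == "trans_only"] = mu0[archs == "trans_only"] * shift[archs == "trans_only"]
    mu_h[archs == "compensatory"] = mu0[archs == "compensatory"] * shift[archs == "compensatory"]

    # combined: HIL mean off both parents — intermediate, reinforced beyond
    # the B parent, or on the far side of N from B, in configured proportions
    comb = np.flatnonzero(archs == "combined")
    sub = rng.choice(3, size=comb.size, p=np.asarray(cfg.combined_weights))
    u = np.where(sub == 0, 0.5, np.where(sub == 1, 1.5, -0.5))
    mu_h[comb] = mu0[comb] * 2.0 ** (sign[comb] * d * u)

    truth = layout.copy()
    truth["architecture"] = archs
    truth["mu_B"] = mu_b
    truth["mu_N"] = mu_n
    truth["mu_H"] = mu_h
    truth["dispersion"] = alpha
    truth["position"] = truth["start"]
    for label, (chrom, s, e) in _introgression_intervals(cfg, layout).items():
        inside = (truth["chrom"] == chrom) & (truth["start"] >= s) & (truth["end"] <= e)
        truth[f"in_introgression_{label}"] = inside
    return truth


def truth_for_hil(truth: pd.DataFrame, label: str) -> pd.DataFrame:
    """Per-HIL view: effective mu_H and a single in_introgression column.

    Introgressed genes carry the donor's cis genotype, so their effective
    HIL mean is mu_B.
    """
    col = f"in_introgression_{label}"
    if col not in truth.columns:
        raise KeyError(f"no introgression flags for HIL {label!r}")
    view = truth[
        ["chrom", "start", "end", "strand", "position", "architecture",
         "mu_B", "mu_N", "mu_H", "dispersion"]
    ].copy()
    view["in_introgression"] = truth[col]
    view.loc[view["in_introgression"], "mu_H"] = view.loc[
        view["in_introgression"], "mu_B"
    ]
    return view


def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorised NB(mean, alpha) with variance mu + alpha*mu^2; alpha=0 is Poisson."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    pos = mean > 0
    m = pois & pos
    if m.any():
        out[m] = rng.poisson(mean[m])
    m = (~pois) & pos
    if m.any():
        size = 1.0 / alpha[m]
        p = size / (size + mean[m])
        out[m] = rng.negative_binomial(size, p)
    return out


def _sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for group in [PARENT_B, PARENT_N] + cfg.hil_labels:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((f"{group}_rep{rep}", group, rep))
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "replicate"])
    return sheet.set_index("sample_id")


def simulate_counts(
    truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple:
    """Draw the dual-reference count matrices for all groups.

    Returns ``(refN CountMatrix, refB CountMatrix, sample sheet,
    library-size factors)``.  Count for gene g in sample j is
    NB(mean = mu_{g, group(j)} * L_j * m, alpha_g) where m is 1 when the
    locus genotype in that sample matches the reference and
    ``cfg.mapping_leak`` otherwise.  The refB matrix is keyed by refB
    gene IDs (the ortholog map of :func:`write_fixture` pairs them).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    samples = _sample_sheet(cfg)
    lib = pd.Series(
        rng.uniform(*cfg.lib_factor_range, size=len(samples)), index=samples.index
    )
    lam = cfg.mapping_leak
    alpha = truth["dispersion"].to_numpy()
    n = len(truth)

    mats = {}
    for tag in ("refN", "refB"):
        cols = {}
        for sid, row in samples.iterrows():
            group = row["group"]
            if group == PARENT_B:
                mu = truth["mu_B"].to_numpy()
                match = np.full(n, tag == "refB")
            elif group == PARENT_N:
                mu = truth["mu_N"].to_numpy()
                match = np.full(n, tag == "refN")
            else:
                view = truth_for_hil(truth, group)
                mu = view["mu_H"].to_numpy()
                intro = view["in_introgression"].to_numpy()
                match = intro if tag == "refB" else ~intro
            mean = mu * lib[sid] * np.where(match, 1.0, lam)
            cols[sid] = _nb_draw(rng, mean, alpha)
        frame = pd.DataFrame(cols, index=truth.index.copy())
        mats[tag] = frame

    ref_b = mats["refB"]
    ref_b.index = pd.Index(
        [g.replace("gN_", "gB_") for g in truth.index], name="gene_id"
    )
    return (
        CountMatrix(mats["refN"], "refN"),
        CountMatrix(ref_b, "refB"),
        samples,
        lib,
    )


def simulate_experiment(cfg: SimConfig) -> dict:
    """End-to-end generation: truth, matrices, metadata — one RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    truth = make_truth(cfg, rng)
    ref_n, ref_b, samples, lib = simulate_counts(truth, cfg, rng)
    orthologs = OrthologMap(
        pd.DataFrame(
            {"gene_id_refB": ref_b.gene_ids, "gene_id_refN": ref_n.gene_ids}
        )
    )
    annotation = truth[["chrom", "start", "end", "strand"]].copy()
    annotation["chrom_class"] = np.where(truth["chrom"] == "X", "X", "autosome")
    return {
        "config": cfg,
        "truth": truth,
        "refN": ref_n,
        "refB": ref_b,
        "samples": samples,
        "lib_factors": lib,
        "orthologs": orthologs,
        "annotation": annotation,
    }


def write_fixture(experiment: dict, outdir) -> dict:
    """Write the simulated experiment as the plain-text formats the
    pipeline consumes.  Deterministic given the config seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_refN": outdir / "counts_refN.tsv",
        "counts_refB": outdir / "counts_refB.tsv",
        "annotation": outdir / "annotation.gff3",
        "orthologs": outdir / "orthologs.tsv",
        "samples": outdir / "samples.csv",
        "truth": outdir / "truth.tsv",
    }
    experiment["refN"].counts.to_csv(paths["counts_refN"], sep="\t", index_label="gene_id")
    experiment["refB"].counts.to_csv(paths["counts_refB"], sep="\t", index_label="gene_id")
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in experiment["annotation"].iterrows():
            fh.write(
                f"{row['chrom']}\thilex\tgene\t{row['start']}\t{row['end']}\t."
                f"\t{row['strand']}\t.\tID={gid}\n"
            )
    experiment["orthologs"].pairs.to_csv(paths["orthologs"], sep="\t", index=False)
    experiment["samples"].to_csv(paths["samples"], index_label="sample_id")
    truth = experiment["truth"].copy()
    truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    return paths


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A no-divergence configuration: every architecture collapses onto
    (mu0, mu0, mu0) by sending the effect size to (numerically) zero."""
    cfg = SimConfig(seed=seed)
    cfg = replace(cfg, effect_size=1e-12, **overrides)
    return cfg
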