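"""Two-group perturbation scoring and gene-set enrichment with FDR control.

Per-gene perturbation between a reference state (group A) and a target state
(group B) is scored with a Welch two-sample t statistic; *undirected* mode
takes its absolute value, making enrichment sensitive to change in either
direction.  A gene set is then tested by comparing the scores of member
genes against all non-member genes with a second Welch t, upper tail
(cutoff-free, in the spirit of mean-rank set tests); an exact or sampled
permutation alternative over random equal-size gene sets is available.
Raw p-values are Benjamini-Hochberg adjusted, and a set is *enriched* when
its q-value falls below alpha.

The enrichment statistic is a pluggable contract: :func:`enrich` accepts any
callable with the :func:`set_statistic` signature, so alternative gene-set
statistics can be substituted without touching the network construction.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_design",
    "filter_genes",
    "gene_scores",
    "welch_t",
    "set_statistic",
    "bh_adjust",
    "enrich",
]

#: smallest reportable p-value; keeps p in (0, 1] when a tail probability
#: underflows to zero (e.g. zero-variance sets)
P_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance matrix with a two-group design.

    ``values`` holds nonnegative abundances (unit-agnostic: counts, FPKM,
    intensities...).  ``design`` maps each sample id to one of exactly two
    group labels; ``group_a`` is the reference state and ``group_b`` the
    target state of the contrast.
    """

    values: pd.DataFrame
    design: dict[str, str]
    group_a: str = field(default="")
    group_b: str = field(default="")

    def __post_init__(self) -> None:
        labels = sorted(set(self.design.values()))
        if len(labels) != 2:
            raise ValueError(f"design must have exactly two group labels, got {labels}")
        if not self.group_a and not self.group_b:
            self.group_a, self.group_b = labels
        elif sorted([self.group_a, self.group_b]) != labels:
            raise ValueError(
                f"groups ({self.group_a!r}, {self.group_b!r}) do not match design labels {labels}"
            )
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        for lab in labels:
            if len(self.samples(lab)) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == group]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, dict(self.design), self.group_a, self.group_b)


def read_expression(
    expr_path, design_path, group_a: str = "", group_b: str = ""
) -> ExpressionMatrix:
    """Read a TSV matrix (first column gene id) plus a two-column design TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    design = read_design(design_path)
    values = values[[c for c in values.columns if c in design]]
    return ExpressionMatrix(values, design, group_a, group_b)


def read_design(path) -> dict[str, str]:
    """Read a sample-to-group map from a headerless two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def filter_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero abundance across every sample, preserving order."""
    mask = (expr.values != 0).any(axis=1)
    if not mask.any():
        raise ValueError("no expressed genes after filtering")
    return expr.with_values(expr.values.loc[mask])


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic for mean(y) - mean(x) and its
    Welch-Satterthwaite degrees of freedom.

    A group of size 1 contributes zero variance (its df term drops out), so
    the statistic stays defined for singleton sets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny = len(x), len(y)
    vx = x.var(ddof=1) if nx_ > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    se2 = vx / nx_ + vy / ny
    diff = y.mean() - x.mean()
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        return t, max(nx_ + ny - 2, 1)
    num = se2**2
    den = 0.0
    if nx_ > 1 and vx > 0:
        den += (vx / nx_) ** 2 / (nx_ - 1)
    if ny > 1 and vy > 0:
        den += (vy / ny) ** 2 / (ny - 1)
    df = num / den if den > 0 else max(nx_ + ny - 2, 1)
    return diff / math.sqrt(se2), df


def gene_scores(
    expr: ExpressionMatrix, directed: bool = False, u_cap: float = 50.0
) -> pd.Series:
    """Per-gene Welch t statistic of group B vs group A.

    Undirected mode (the default) returns the absolute statistic, so up- and
    down-perturbations count alike.  Genes with zero variance in both groups
    score 0 when the means agree and +/- ``u_cap`` when they differ — a
    finite stand-in for an infinite t that preserves their extreme rank.
    """
    a = expr.values[expr.samples(expr.group_a)].to_numpy(dtype=float)
    b = expr.values[expr.samples(expr.group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * u_cap
    t = np.clip(t, -u_cap, u_cap)
    scores = pd.Series(t, index=expr.genes, name="t")
    return scores if directed else scores.abs().rename("u")


def set_statistic(
    scores: pd.Series,
    members: frozenset[str] | set[str],
    mode: str = "parametric",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Test whether member genes score higher than the rest of the genome.

    Parametric mode: Welch t of member vs non-member scores with an
    upper-tail Student-t p-value (Welch-Satterthwaite df).  Permutation
    mode: p = (1 + #{random equal-size gene sets with mean score >= observed
    mean}) / (1 + n_perm), the add-one correction keeping p > 0; with
    ``exhaustive=True`` every subset of the scored genes is enumerated
    instead of sampled.
    """
    member_mask = scores.index.isin(members)
    x = scores.to_numpy(dtype=float)[member_mask]
    y = scores.to_numpy(dtype=float)[~member_mask]
    if len(x) == 0:
        raise ValueError("no member gene has a score")
    if len(y) < 2:
        raise ValueError("fewer than 2 non-member genes; set statistic undefined")
    t, df = welch_t(y, x)  # member mean minus non-member mean
    if mode == "parametric":
        p = float(stats.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
        return t, max(min(p, 1.0), P_FLOOR)
    if mode != "permutation":
        raise ValueError(f"unknown mode: {mode!r}")
    values = scores.to_numpy(dtype=float)
    m = len(x)
    observed = x.mean()
    if exhaustive:
        count = sum(
            1
            for combo in itertools.combinations(range(len(values)), m)
            if values[list(combo)].mean() >= observed
        )
        total = math.comb(len(values), m)
        return t, (1 + count) / (1 + total)
    if rng is None:
        rng = np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        draw = rng.choice(len(values), size=m, replace=False)
        if values[draw].mean() >= observed:
            count += 1
    return t, (1 + count) / (1 + n_perm)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _set_seed(master: int | None, set_id: str) -> int | None:
    """Per-set RNG seed, stable under set ordering."""
    if master is None:
        return None
    return (master + zlib.crc32(set_id.encode())) % (2**31)


def enrich(
    expr: ExpressionMatrix,
    sets,
    alpha: float = 0.05,
    *,
    directed: bool = False,
    u_cap: float = 50.0,
    min_set_size: int = 2,
    mode: str = "parametric",
    n_perm: int = 1000,
    seed: int | None = None,
    statistic=set_statistic,
) -> pd.DataFrame:
    """Score every gene set and flag those enriched at q < alpha.

    ``sets`` is an iterable of (id, gene set).  Sets whose overlap with the
    scored genes is below ``min_set_size`` are reported untested (NaN p and
    q).  BH adjustment runs across all sets tested in this call, so pathway
    and crosstalk-region runs form separate multiple-testing families.
    """
    sets = list(sets)
    if not sets:
        return pd.DataFrame(
            columns=["set_id", "size", "statistic", "p", "q", "tested", "enriched"]
        )
    scores = gene_scores(expr, directed=directed, u_cap=u_cap)
    n_scored = len(scores)
    rows = []
    for set_id, genes in sets:
        overlap = scores.index.isin(genes).sum()
        testable = overlap >= max(min_set_size, 1) and overlap < n_scored - 1
        t_stat = p = np.nan
        if testable:
            rng = (
                np.random.default_rng(_set_seed(seed, str(set_id)))
                if mode == "permutation"
                else None
            )
            t_stat, p = statistic(scores, frozenset(genes), mode=mode, n_perm=n_perm, rng=rng)
        rows.append(
            {"set_id": set_id, "size": int(overlap), "statistic": t_stat, "p": p,
             "tested": bool(testable)}
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"])
    table["enriched"] = table["q"] < alpha  # NaN q compares False
    return table
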