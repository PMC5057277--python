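"""Per-KO differential-abundance testing between sample groups.

Two test methods operate on RPKM values: the Kruskal-Wallis rank-sum test
(default; tie-corrected H referenced to chi-square with k-1 df) and a
quasi-Poisson GLM (log link, group factor, dispersion estimated as Pearson
X^2 / (n - k), Wald coefficient tests referenced to Student-t). A KO is
called differentially abundant (DA) when its selected p-value (raw or
BH-adjusted) is below alpha AND |log2 fold change| exceeds the threshold —
both comparisons strict. The zero-inflated Gaussian method of metagenomeSeq
is an external extension point and deliberately not re-implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fmapy.quantify import AbundanceTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_PSEUDOCOUNT = 1e-3  # RPKM units; zero-handling for fold changes

QP_MAX_ITER = 50
QP_TOL = 1e-8


class DegenerateFitWarning(UserWarning):
    """A GLM fit was degenerate (e.g. an all-zero group); p = 1 returned."""


@dataclass
class DesignTable:
    """sample -> group mapping with an ordered group list.

    The first group label is the reference (control); fold changes are
    case vs reference.
    """

    assignments: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        if not self.groups:
            self.groups = seen
        if len(self.groups) < 2:
            raise ValueError("design must contain at least 2 groups")
        counts = pd.Series(list(self.assignments.values())).value_counts()
        small = [g for g in self.groups if counts.get(g, 0) < 2]
        if small:
            raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    @property
    def reference(self) -> str:
        return self.groups[0]

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @classmethod
    def from_tsv(cls, path: Path | str, reference: str | None = None) -> "DesignTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"sample_id", "group"}.issubset(df.columns):
            raise ValueError(f"{path}: design table needs columns sample_id, group")
        assignments = dict(zip(df["sample_id"], df["group"]))
        design = cls(assignments=assignments)
        if reference is not None:
            if reference not in design.groups:
                raise ValueError(f"reference group {reference!r} not in design")
            design.groups = [reference] + [g for g in design.groups if g != reference]
        return design


@dataclass
class ComparisonResult:
    """Per-KO test results: p/q-values, log2 fold changes, DA flags."""

    table: pd.DataFrame  # index ko_id; p_value, q_value, log2_fc, mean_<g>, is_da
    method: str
    reference_group: str
    case_group: str
    alpha: float
    min_abs_log2fc: float
    filter_on: str

    @property
    def da_kos(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_da"]])

    def log2fc_of(self, ko_id: str) -> float:
        return float(self.table.loc[ko_id, "log2_fc"])

    def write_tsv(self, out_path: Path | str) -> None:
        out = self.table.copy()
        out.index.name = "ko_id"
        out.to_csv(out_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: Path | str,
        method: str = "kruskal",
        alpha: float = DEFAULT_ALPHA,
        min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
        filter_on: str = "raw",
    ) -> "ComparisonResult":
        df = pd.read_csv(path, sep="\t", index_col="ko_id")
        df["is_da"] = df["is_da"].astype(bool)
        mean_cols = [c for c in df.columns if c.startswith("mean_")]
        groups = [c.removeprefix("mean_") for c in mean_cols]
        return cls(
            table=df,
            method=method,
            reference_group=groups[0] if groups else "",
            case_group=groups[1] if len(groups) > 1 else "",
            alpha=alpha,
            min_abs_log2fc=min_abs_log2fc,
            filter_on=filter_on,
        )


def _split_groups(
    values: Sequence[float], groups: Sequence[str]
) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[g] = values[groups == g]
        if out[g].size < 1:
            raise ValueError(f"group {g!r} has no observations")
    if len(out) < 2:
        raise ValueError("at least 2 groups required")
    return out


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> float:
    """Tie-corrected Kruskal-Wallis p-value (chi-square, k-1 df).

    An all-tied input (every value identical) carries no rank information and
    returns p = 1 by contract.
    """
    by_group = _split_groups(values, groups)
    arrays = list(by_group.values())
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 1.0
    _, p = stats.kruskal(*arrays)
    return float(p)


def quasi_poisson_test(values: Sequence[float], groups: Sequence[str]) -> float:
    """Quasi-Poisson GLM p-value for the group factor on nonnegative values.

    Log link, IRLS fit, dispersion phi = Pearson X^2 / (n - k). For two
    groups the returned p is the two-sided Wald test of the group coefficient
    with Student-t reference at n - k df; for k > 2 groups an F-test of the
    whole group factor is returned. A group with an all-zero mean makes the
    log-link fit degenerate: p = 1 is returned with a warning.
    """
    import statsmodels.api as sm

    by_group = _split_groups(values, groups)
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("quasi-Poisson requires nonnegative values")
    if any(arr.mean() == 0 for arr in by_group.values()):
        warnings.warn(
            "a group has an all-zero mean; quasi-Poisson fit is degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return 1.0
    flat = np.concatenate(list(by_group.values()))
    if np.all(flat == flat[0]):
        return 1.0

    labels = list(by_group)
    k = len(labels)
    n = vals.size
    y = np.concatenate([by_group[g] for g in labels])
    design = np.zeros((n, k))
    design[:, 0] = 1.0
    pos = 0
    for j, g in enumerate(labels):
        m = by_group[g].size
        if j > 0:
            design[pos : pos + m, j] = 1.0
        pos += m

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer endog is fine for quasi-likelihood
        model = sm.GLM(y, design, family=sm.families.Poisson())
        res = model.fit(maxiter=QP_MAX_ITER, tol=QP_TOL)
    if not res.converged:
        raise RuntimeError(f"quasi-Poisson IRLS did not converge in {QP_MAX_ITER} iterations")

    mu = res.fittedvalues
    x2 = float(((y - mu) ** 2 / mu).sum())
    df_resid = n - k
    phi = x2 / df_resid
    if phi <= 0:
        return 1.0 if np.all(mu == mu[0]) else 0.0
    cov = res.cov_params(scale=phi)
    coefs = res.params[1:]
    ses = np.sqrt(np.diag(cov)[1:])
    if k == 2:
        t = coefs[0] / ses[0]
        return float(2 * stats.t.sf(abs(t), df=df_resid))
    # k > 2: Wald F-test of all non-reference coefficients
    sub_cov = cov[1:, 1:]
    f = float(coefs @ np.linalg.solve(sub_cov, coefs)) / (k - 1)
    return float(stats.f.sf(f, k - 1, df_resid))


def log2_fold_change(
    mean_case: float, mean_ref: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((mean_case + c) / (mean_ref + c)) with pseudocount c > 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if mean_case < 0 or mean_ref < 0:
        raise ValueError("group means must be nonnegative")
    return float(np.log2((mean_case + pseudocount) / (mean_ref + pseudocount)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


_METHODS = {"kruskal": kruskal_wallis, "quasipoisson": quasi_poisson_test}


def run_comparison(
    table: AbundanceTable,
    design: DesignTable,
    method: str = "kruskal",
    filter_on: str = "raw",
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ComparisonResult:
    """Test every KO in the table for differential abundance across groups.

    Both available methods consume RPKM. KOs with zero abundance in every
    design sample are excluded before testing (the count is logged). The DA
    flag is (selected p < alpha) AND (|log2_fc| > min_abs_log2fc), where the
    selected p is raw (``filter_on='raw'``) or BH-adjusted
    (``filter_on='fdr'``), and log2_fc compares the first non-reference group
    against the reference.
    """
    if method == "metagenomeseq":
        raise NotImplementedError(
            "metagenomeseq is not implemented; it is an external extension "
            "point (use the metagenomeSeq R package on the raw-count table)"
        )
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose kruskal|quasipoisson")
    if filter_on not in {"raw", "fdr"}:
        raise ValueError(f"filter_on must be 'raw' or 'fdr', got {filter_on!r}")
    missing = [s for s in design.assignments if s not in table.samples]
    if missing:
        raise ValueError(f"design sample(s) absent from table: {missing}")
    test = _METHODS[method]

    samples = [s for s in table.samples if s in design.assignments]
    labels = [design.assignments[s] for s in samples]
    mat = table.rpkm[samples]
    nonzero = mat.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("run_comparison: dropped %d all-zero KO(s) before testing", n_dropped)
    mat = mat[nonzero]

    ref = design.reference
    case = next(g for g in design.groups if g != ref)
    rows = []
    for ko, row in mat.iterrows():
        vals = row.to_numpy(dtype=float)
        p = test(vals, labels)
        means = {g: float(row[design.samples_of(g)].mean()) for g in design.groups}
        lfc = log2_fold_change(means[case], means[ref], pseudocount)
        rows.append({"ko_id": ko, "p_value": p, "log2_fc": lfc, **{f"mean_{g}": means[g] for g in design.groups}})
    out = pd.DataFrame(rows).set_index("ko_id") if rows else pd.DataFrame(
        columns=["p_value", "log2_fc"]
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].tolist())
        selected = out["p_value"] if filter_on == "raw" else out["q_value"]
        out["is_da"] = (selected < alpha) & (out["log2_fc"].abs() > min_abs_log2fc)
        cols = ["p_value", "q_value", "log2_fc"] + [f"mean_{g}" for g in design.groups] + ["is_da"]
        out = out[cols]
    return ComparisonResult(
        table=out,
        method=method,
        reference_group=ref,
        case_group=case,
        alpha=alpha,
        min_abs_log2fc=min_abs_log2fc,
        filter_on=filter_on,
    )
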