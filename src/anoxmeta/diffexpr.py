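"""Bayesian-regularized differential expression for replicated microarrays.

The model is a two-group regularized t-test in the Cyber-T family: each
gene's within-group variance is shrunk toward a local background variance
estimated from the genes nearest in mean expression (a sliding rank
window), reflecting the strong mean-variance coupling of array data.  With
prior weight ``v0`` (pseudo-replicates) and observed within-group variance
``s^2`` over ``n`` replicates, the regularized variance is the convex
combination

    sigma~^2 = (v0 * sigma0^2 + (n - 1) * s^2) / (v0 + n - 1),

where ``sigma0`` is the windowed background sd.  The statistic

    t = (m_b - m_a) / sqrt(sigma~_a^2 / n_a + sigma~_b^2 / n_b)

is referred to a Student distribution with ``n_a + n_b - 2 + 2*v0``
degrees of freedom (the prior contributes pseudo-observations to each
group).  At ``v0 = 0`` the statistic reduces exactly to the classical
Welch t on the observed sds.

Significance is summarized two ways: the two-sided p-value, and the
posterior probability of differential expression (PPDE) from a
beta-uniform mixture fitted to the contrast's p-values,

    f(p) = lambda + (1 - lambda) * a * p^(a - 1),      0 < p <= 1,

with PPDE(p) the posterior weight of the beta (alternative) component.
A gene is called up (down) when all three of |fold| > fold threshold,
p < p threshold and PPDE > PPDE threshold hold (defaults 2-fold, 0.05,
0.96).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionStudy, ValidationError

__all__ = [
    "CyberTParams",
    "Thresholds",
    "ContrastSpec",
    "CyberT",
    "ContrastResults",
    "BumModel",
    "BumResults",
    "BumConvergenceError",
    "background_sd",
    "regularized_variance",
    "cybert_contrast",
    "fit_bum_ppde",
    "call_de",
    "stepwise_contrasts",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CyberTParams:
    """Tuning constants of the regularized t-test.

    window_size : odd number of rank-neighbouring genes pooled for the
        background sd (101 — the classic web-server default).
    prior_df : weight v0 of the background variance, in pseudo-replicates
        (10 by default; 0 disables regularization entirely).
    variance_floor : lower bound applied to observed variances so that
        zero-variance (tied) genes remain testable.
    df_mode : "regularized" uses n_a + n_b - 2 + 2*v0 degrees of freedom,
        "classical" uses n_a + n_b - 2.
    """

    window_size: int = 101
    prior_df: float = 10.0
    variance_floor: float = 1e-8
    df_mode: str = "regularized"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValidationError("window_size must be odd and >= 1")
        if self.prior_df < 0:
            raise ValidationError("prior_df (v0) must be >= 0")
        if self.variance_floor <= 0:
            raise ValidationError("variance_floor must be positive")
        if self.df_mode not in ("regularized", "classical"):
            raise ValidationError("df_mode must be 'regularized' or 'classical'")


@dataclass(frozen=True)
class Thresholds:
    """The three-part differential-expression call rule."""

    fold: float = 2.0
    p: float = 0.05
    ppde: float = 0.96

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValidationError("fold threshold must be >= 1 (linear scale)")
        if not (0 < self.p <= 1):
            raise ValidationError("p threshold must lie in (0, 1]")
        if not (0 <= self.ppde <= 1):
            raise ValidationError("ppde threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison within a study.

    ``group_a`` is the reference, ``group_b`` the treatment; ``orientation``
    of -1 flips the sign of the reported log2 fold-changes (used when a
    published comparison ran the other way around and the response to the
    stress is wanted).
    """

    study_id: str
    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    orientation: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if set(self.group_a) & set(self.group_b):
            raise ValidationError(f"contrast '{self.name}': groups are not disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValidationError(
                f"contrast '{self.name}': each group needs >= 2 replicate samples"
            )
        if self.orientation not in (1, -1):
            raise ValidationError("orientation must be +1 or -1")

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(
            self.study_id, self.name, self.group_b, self.group_a, self.orientation
        )


# ---------------------------------------------------------------------------
# Background variance
# ---------------------------------------------------------------------------

def background_sd(
    gene_means: np.ndarray, gene_sds: np.ndarray, window_size: int
) -> np.ndarray:
    """Windowed background sd: for each gene, the root-mean-square of the
    sds of the ``window_size`` genes nearest in rank of mean expression,
    centered on the gene and truncated at the edges.

    ``window_size`` larger than the number of genes is clipped.
    """
    means = np.asarray(gene_means, dtype=float)
    sds = np.asarray(gene_sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1:
        raise ValidationError("gene_means and gene_sds must be aligned 1-d arrays")
    n = means.size
    if n < 2:
        raise ValidationError("need at least 2 genes to estimate a background sd")
    if window_size < 1 or window_size % 2 == 0:
        raise ValidationError("window_size must be odd and >= 1")
    w = min(window_size, n if n % 2 == 1 else n - 1)
    half = w // 2
    order = np.argsort(means, kind="stable")
    sq = sds[order] ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + half + 1, None, n)
    win_mean = (csum[hi] - csum[lo]) / (hi - lo)
    out = np.empty(n)
    out[order] = np.sqrt(win_mean)
    return out


def regularized_variance(
    obs_var: np.ndarray | float, bg_var: np.ndarray | float, n: int, v0: float
) -> np.ndarray | float:
    """Convex shrinkage of the observed variance toward the background:
    ``(v0*bg + (n-1)*obs) / (v0 + n - 1)``; ``v0=0`` returns obs unchanged."""
    if v0 == 0:
        return obs_var
    return (v0 * bg_var + (n - 1) * obs_var) / (v0 + n - 1)


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

class ContrastResults:
    """Per-gene estimates for one contrast.

    Carries log2 fold-change (treatment minus reference on the log2 scale,
    orientation applied), the regularized t, its two-sided p-value, the
    PPDE once :meth:`add_ppde` has run, and the up/down/ns call once
    :meth:`with_calls` has run.  ``summary()`` prints a compact report.
    """

    _COLUMNS = ["log2fc", "t", "p", "ppde", "call"]

    def __init__(
        self,
        spec: ContrastSpec,
        params: CyberTParams,
        table: pd.DataFrame,
        bum: "BumResults | None" = None,
        thresholds: Thresholds | None = None,
    ) -> None:
        self.spec = spec
        self.params = params
        self.table = table
        self.bum = bum
        self.thresholds = thresholds

    # -- accessors -------------------------------------------------------------
    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def t_stat(self) -> pd.Series:
        return self.table["t"]

    @property
    def p_value(self) -> pd.Series:
        return self.table["p"]

    @property
    def ppde(self) -> pd.Series:
        return self.table["ppde"]

    @property
    def call(self) -> pd.Series:
        return self.table["call"]

    def up_genes(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    def down_genes(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    def de_genes(self) -> set[str]:
        return self.up_genes() | self.down_genes()

    # -- pipeline steps --------------------------------------------------------
    def add_ppde(self, bum: "BumResults | None" = None, seed: int = 0) -> "ContrastResults":
        """Attach PPDE values, fitting the beta-uniform mixture to this
        contrast's p-values unless a fitted ``bum`` is supplied."""
        if bum is None:
            bum = BumModel(self.table["p"].to_numpy()).fit(seed=seed)
        table = self.table.copy()
        table["ppde"] = bum.ppde(table["p"].to_numpy())
        return ContrastResults(self.spec, self.params, table, bum=bum, thresholds=self.thresholds)

    def with_calls(self, thresholds: Thresholds = Thresholds()) -> "ContrastResults":
        """Apply the three-part call rule (fold, p, PPDE); requires PPDE."""
        if self.table["ppde"].isna().any():
            raise ValidationError("PPDE not populated; run add_ppde() before calling")
        table = self.table.copy()
        lfc_min = np.log2(thresholds.fold)
        sig = (table["p"] < thresholds.p) & (table["ppde"] > thresholds.ppde)
        call = np.where(
            sig & (table["log2fc"] > lfc_min),
            "up",
            np.where(sig & (table["log2fc"] < -lfc_min), "down", "ns"),
        )
        table["call"] = call
        return ContrastResults(self.spec, self.params, table, bum=self.bum, thresholds=thresholds)

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Regularized t contrast results",
            "==============================",
            f"study:      {self.spec.study_id}",
            f"contrast:   {self.spec.name} "
            f"(n_a={len(self.spec.group_a)}, n_b={len(self.spec.group_b)}, "
            f"orientation={self.spec.orientation:+d})",
            f"genes:      {len(self.table)}",
            f"window:     {self.params.window_size}   v0: {self.params.prior_df}   "
            f"df mode: {self.params.df_mode}",
        ]
        if self.bum is not None:
            lines.append(
                f"BUM mixture: lambda={self.bum.lambda_:.4f}  a={self.bum.a:.4f}  "
                f"loglik={self.bum.loglik:.2f}"
            )
        if not self.table["call"].isna().all() and self.thresholds is not None:
            th = self.thresholds
            up, down = len(self.up_genes()), len(self.down_genes())
            lines += [
                f"call rule:  |fold| > {th.fold:g}, p < {th.p:g}, PPDE > {th.ppde:g}",
                f"calls:      up={up}  down={down}  ns={len(self.table) - up - down}",
            ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(
        cls,
        path: str,
        spec: ContrastSpec | None = None,
        name: str | None = None,
    ) -> "ContrastResults":
        """Rehydrate a results table written by :meth:`to_tsv`.

        The group structure is not stored in the TSV; a placeholder spec is
        built from ``name`` when none is given (enough for the consensus
        stages, which only use gene-level columns)."""
        table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        table.index = table.index.astype(str)
        if spec is None:
            spec = ContrastSpec(
                study_id="?", name=name or path, group_a=("a1", "a2"), group_b=("b1", "b2")
            )
        for col in cls._COLUMNS:
            if col not in table.columns:
                table[col] = np.nan
        if "call" in table.columns:
            table["call"] = table["call"].astype(object)
        return cls(spec, CyberTParams(), table[cls._COLUMNS])


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

class CyberT:
    """Regularized two-group t-test model for one contrast of a study.

    Examples
    --------
    >>> model = CyberT(study, spec)           # doctest: +SKIP
    >>> res = model.fit().add_ppde(seed=0).with_calls()   # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    def __init__(
        self,
        study: ExpressionStudy,
        contrast: ContrastSpec,
        params: CyberTParams | None = None,
    ) -> None:
        self.study = study
        self.contrast = contrast
        self.params = params or CyberTParams()
        missing = [
            s
            for s in (*contrast.group_a, *contrast.group_b)
            if s not in study.sample_ids
        ]
        if missing:
            raise ValidationError(
                f"contrast '{contrast.name}' names samples absent from study "
                f"'{study.study_id}': {missing}"
            )

    def fit(self) -> ContrastResults:
        p = self.params
        spec = self.contrast
        A = self.study.values[list(spec.group_a)].to_numpy(dtype=float)
        B = self.study.values[list(spec.group_b)].to_numpy(dtype=float)
        na, nb = A.shape[1], B.shape[1]
        ma, mb = A.mean(axis=1), B.mean(axis=1)
        va_raw, vb_raw = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
        if p.prior_df == 0 and np.all(va_raw == 0) and np.all(vb_raw == 0):
            raise ValidationError(
                "every gene has zero within-group variance and v0=0: nothing to "
                "test; raise prior_df or rely on the variance floor"
            )
        va = np.maximum(va_raw, p.variance_floor)
        vb = np.maximum(vb_raw, p.variance_floor)
        bg_a = background_sd(ma, np.sqrt(va), p.window_size) ** 2
        bg_b = background_sd(mb, np.sqrt(vb), p.window_size) ** 2
        reg_a = regularized_variance(va, bg_a, na, p.prior_df)
        reg_b = regularized_variance(vb, bg_b, nb, p.prior_df)
        se = np.sqrt(reg_a / na + reg_b / nb)
        diff = mb - ma
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        if p.df_mode == "regularized":
            df = na + nb - 2 + 2 * p.prior_df
        else:
            df = na + nb - 2
        pval = np.clip(2.0 * stats.t.sf(np.abs(t), df), 1e-300, 1.0)
        table = pd.DataFrame(
            {
                "log2fc": diff * spec.orientation,
                "t": t,
                "p": pval,
                "ppde": np.nan,
                "call": pd.array([None] * len(diff), dtype=object),
            },
            index=self.study.values.index,
        )
        return ContrastResults(spec, p, table)


def cybert_contrast(
    study: ExpressionStudy, spec: ContrastSpec, params: CyberTParams | None = None
) -> ContrastResults:
    """Functional facade over :class:`CyberT` (fit only; no PPDE/calls)."""
    return CyberT(study, spec, params).fit()


def call_de(
    results: ContrastResults,
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
    ppde_threshold: float = 0.96,
) -> ContrastResults:
    """Apply the three-part up/down/ns rule to a PPDE-bearing result."""
    return results.with_calls(Thresholds(fold_threshold, p_threshold, ppde_threshold))


# ---------------------------------------------------------------------------
# Step-wise time-course contrasts
# ---------------------------------------------------------------------------

def stepwise_contrasts(
    study: ExpressionStudy, condition_series: Sequence[str]
) -> list[ContrastSpec]:
    """Each time point against the previous one, in series order.

    For k timepoints returns k-1 specs named ``"t_i v t_{i-1}"`` with the
    earlier timepoint as reference.  A timepoint with fewer than 2
    replicates is an error; a single timepoint yields an empty list.
    """
    series = list(condition_series)
    groups: list[tuple[str, list[str]]] = []
    for cond in series:
        samples = study.samples_for(cond)
        if cond not in study.conditions:
            raise ValidationError(f"condition '{cond}' not present in study '{study.study_id}'")
        groups.append((cond, samples))
    if len(series) >= 2:
        for cond, samples in groups:
            if len(samples) < 2:
                raise ValidationError(
                    f"timepoint '{cond}' has {len(samples)} replicate(s); need >= 2"
                )
    specs = []
    for (prev, prev_s), (curr, curr_s) in zip(groups, groups[1:]):
        specs.append(
            ContrastSpec(
                study_id=study.study_id,
                name=f"{curr} v {prev}",
                group_a=tuple(prev_s),
                group_b=tuple(curr_s),
                orientation=1,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Beta-uniform mixture / PPDE
# ---------------------------------------------------------------------------

class BumConvergenceError(RuntimeError):
    """EM failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_fit: "BumResults | None" = None) -> None:
        super().__init__(message)
        self.last_fit = last_fit


@dataclass(frozen=True)
class BumResults:
    """Fitted beta-uniform mixture over p-values.

    ``lambda_`` is the weight of the uniform (null) component and ``a`` the
    beta shape (a <= 1 concentrates the alternative near p = 0).
    """

    lambda_: float
    a: float
    loglik: float
    n_obs: int
    n_iter: int
    converged: bool

    def density(self, p: np.ndarray | float) -> np.ndarray | float:
        p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0)
        return self.lambda_ + (1.0 - self.lambda_) * self.a * p ** (self.a - 1.0)

    def ppde(self, p: np.ndarray | float) -> np.ndarray | float:
        """Posterior probability that a p-value came from the alternative."""
        p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0)
        alt = (1.0 - self.lambda_) * self.a * p ** (self.a - 1.0)
        return alt / (self.lambda_ + alt)

    def summary(self) -> str:
        return (
            "Beta-uniform mixture fit\n"
            "------------------------\n"
            f"n p-values: {self.n_obs}\n"
            f"lambda (null weight): {self.lambda_:.4f}\n"
            f"a (beta shape):       {self.a:.4f}\n"
            f"log-likelihood:       {self.loglik:.3f}\n"
            f"EM iterations:        {self.n_iter} (converged={self.converged})"
        )


class BumModel:
    """Maximum-likelihood beta-uniform mixture, fitted by EM.

    The complete-data problem has closed-form M-steps: with posterior
    alternative weights w_i, lambda = 1 - mean(w) and the beta(a, 1) shape
    a = -sum(w) / sum(w * log p).  Random restarts guard against the flat
    likelihood ridge near lambda = 1.
    """

    def __init__(self, pvalues: Iterable[float]) -> None:
        p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                       dtype=float)
        if p.size == 0:
            raise ValidationError("no p-values supplied")
        if np.any(~np.isfinite(p)) or np.any(p > 1) or np.any(p < 0):
            raise ValidationError("p-values must be finite and within [0, 1]")
        self.p = np.clip(p, 1e-12, 1.0)
        self.logp = np.log(self.p)

    def _em(self, lam: float, a: float, max_iter: int, tol: float):
        p, logp = self.p, self.logp
        prev_ll = -np.inf
        prev_lam, prev_a = lam, a
        for it in range(1, max_iter + 1):
            alt = (1.0 - lam) * a * p ** (a - 1.0)
            f = lam + alt
            w = alt / f
            ll = float(np.sum(np.log(f)))
            # converge on either the likelihood or the parameters: near the
            # degenerate a->1 ridge the likelihood creeps (~1e-8/iter)
            # while the parameters have effectively stopped moving
            if abs(ll - prev_ll) < tol or (
                it > 1 and abs(lam - prev_lam) < 1e-9 and abs(a - prev_a) < 1e-9
            ):
                return lam, a, ll, it, True
            prev_ll = ll
            prev_lam, prev_a = lam, a
            wsum = float(w.sum())
            lam = min(max(1.0 - wsum / p.size, 0.0), 1.0 - 1e-10)
            denom = float(np.sum(w * logp))
            if wsum <= 1e-12 or denom >= -1e-300:
                a = 1.0
            else:
                a = min(max(-wsum / denom, 1e-4), 1.0)
        return lam, a, prev_ll, max_iter, False

    def fit(
        self,
        n_restarts: int = 10,
        seed: int = 0,
        max_iter: int = 2000,
        tol: float = 1e-6,
    ) -> BumResults:
        """Best EM fit over seeded random restarts.

        The mixture is unidentifiable when the data are truly uniform (at
        a = 1 every lambda gives the same density), so the fitted mixture
        is compared by BIC against the degenerate all-null model
        (lambda = 1); when the mixture does not earn its two parameters
        the all-null fit is returned, giving PPDE = 0 everywhere.
        """
        rng = np.random.default_rng(seed)
        starts = [(0.5, 0.5)] + [
            (rng.uniform(0.2, 0.95), rng.uniform(0.05, 0.95)) for _ in range(n_restarts - 1)
        ]
        best: BumResults | None = None
        last: BumResults | None = None
        for lam0, a0 in starts:
            lam, a, ll, it, conv = self._em(lam0, a0, max_iter, tol)
            fit = BumResults(lam, a, ll, self.p.size, it, conv)
            last = fit
            if conv and (best is None or ll > best.loglik):
                best = fit
        if best is None:
            raise BumConvergenceError(
                f"beta-uniform EM did not converge in {max_iter} iterations from "
                f"{len(starts)} starts; consider more iterations or looser tol",
                last_fit=last,
            )
        # BIC model selection against the pure-uniform null (0 parameters,
        # log-likelihood exactly 0)
        bic_mixture = 2.0 * np.log(self.p.size) - 2.0 * best.loglik
        if bic_mixture >= 0.0:
            return BumResults(1.0, 1.0, 0.0, self.p.size, 0, True)
        return best


def fit_bum_ppde(
    p_values: Iterable[float],
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[BumResults, np.ndarray]:
    """Fit the beta-uniform mixture and return (fit, per-gene PPDE)."""
    model = BumModel(p_values)
    fit = model.fit(n_restarts=n_restarts, seed=seed, max_iter=max_iter, tol=tol)
    return fit, np.asarray(fit.ppde(model.p))
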