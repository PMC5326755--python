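"""Mixed-effects models with planned contrasts, and the 2x2 decomposition.

Simulated naming latencies (cycles) are analysed with linear mixed-effects
models containing a random intercept per word and a saturated cell-means
fixed-effects structure (stimulus quality as a categorical factor crossed
with frequency band, and optionally with feedback presence).  Planned
contrasts are explicit linear combinations of cell means, so each 2x2
pairing of the clear condition (100%) with a degraded level yields a word
frequency main effect, a simple stimulus-quality effect for high-frequency
words, and their interaction -- mirroring a factorial human experiment.

Variance components are estimated by REML (via statsmodels ``MixedLM``);
contrast standard errors and Satterthwaite-style denominator degrees of
freedom are computed from the fitted variance components with the standard
delta-method formula ``df = 2 g^2 / (grad' A grad)``, where ``g`` is the
contrast variance, ``grad`` its gradient with respect to the variance
components, and ``A`` their asymptotic (REML expected-information)
covariance.  When the random-intercept variance collapses to zero the fit
falls back to ordinary least squares with residual degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = ("contrast", "estimate", "se", "df", "t", "p")


class AnalysisError(ValueError):
    """Raised for schema violations or impossible contrast requests."""


# --------------------------------------------------------------------------
# 2x2 factorial decomposition (the human-experiment arithmetic)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectTable2x2:
    """Cell means and derived effects for one 2 (SQ) x 2 (WF) table.

    ``sq_effect_*`` is degraded minus clear within a band; ``wf_effect_*``
    is low-frequency minus high-frequency within a quality level; the
    interaction is the difference of the two stimulus-quality effects
    (low-frequency minus high-frequency), i.e. over-additivity when
    positive.
    """

    lf_high_sq: float
    lf_low_sq: float
    hf_high_sq: float
    hf_low_sq: float

    @property
    def sq_effect_lf(self) -> float:
        return self.lf_low_sq - self.lf_high_sq

    @property
    def sq_effect_hf(self) -> float:
        return self.hf_low_sq - self.hf_high_sq

    @property
    def wf_effect_high_sq(self) -> float:
        return self.lf_high_sq - self.hf_high_sq

    @property
    def wf_effect_low_sq(self) -> float:
        return self.lf_low_sq - self.hf_low_sq

    @property
    def interaction(self) -> float:
        return self.sq_effect_lf - self.sq_effect_hf


def factorial_effects(
    lf_high_sq: float, lf_low_sq: float, hf_high_sq: float, hf_low_sq: float
) -> EffectTable2x2:
    """Decompose four cell means into simple effects and the interaction."""
    cells = (lf_high_sq, lf_low_sq, hf_high_sq, hf_low_sq)
    if not all(np.isfinite(cells)):
        raise AnalysisError(f"cell means must be finite, got {cells}")
    return EffectTable2x2(*map(float, cells))


def cell_means_2x2(trials: pd.DataFrame, low_sq: int) -> EffectTable2x2:
    """Build the 2x2 table from a trial table (one ia x locus cell)."""
    sub = trials[trials["sq_percent"].isin([100, low_sq])]
    means = sub.groupby(["band", "sq_percent"])["cycles"].mean()
    try:
        return factorial_effects(
            lf_high_sq=means[("low", 100)],
            lf_low_sq=means[("low", low_sq)],
            hf_high_sq=means[("high", 100)],
            hf_low_sq=means[("high", low_sq)],
        )
    except KeyError as exc:
        raise AnalysisError(f"missing cell for pairing 100/{low_sq}: {exc}") from exc


# --------------------------------------------------------------------------
# Mixed model with random intercept per word
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    """One planned contrast: estimate, SE, denominator df, t and p."""

    label: str
    estimate: float
    se: float
    df: float
    t: float
    p: float


@dataclass
class LMEFit:
    """A fitted random-intercept cell-means model.

    ``beta`` maps cell keys (tuples of factor levels) to fixed-effect cell
    means.  ``sigma_b2``/``sigma_e2`` are the REML random-intercept and
    residual variances; ``singular`` marks the zero-variance (OLS) fallback,
    in which case contrast df are residual rather than Satterthwaite.
    """

    cells: list[tuple]
    beta: np.ndarray
    sigma_b2: float
    sigma_e2: float
    X: np.ndarray
    group_labels: np.ndarray
    n_obs: int
    factors: list[str]
    singular: bool = False
    converged: bool = True

    @property
    def df_method(self) -> str:
        return "residual" if self.singular else "satterthwaite"

    def cell_index(self, key: tuple) -> int:
        try:
            return self.cells.index(key)
        except ValueError:
            raise AnalysisError(f"unknown cell {key!r}; cells are {self.cells}")

    def contrast_vector(self, coeffs: Mapping[tuple, float]) -> np.ndarray:
        c = np.zeros(len(self.cells))
        for key, value in coeffs.items():
            c[self.cell_index(key)] = value
        return c

    def contrast(self, coeffs: Mapping[tuple, float], label: str) -> ContrastResult:
        """Estimate a linear combination of cell means with Satterthwaite df."""
        c = self.contrast_vector(coeffs)
        estimate = float(c @ self.beta)
        var, df = _contrast_variance_and_df(
            self.X, self.group_labels, self.sigma_b2, self.sigma_e2, c,
            residual_df=self.n_obs - len(self.cells),
            satterthwaite=not self.singular,
        )
        se = float(np.sqrt(var))
        t = estimate / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(df) else float("nan")
        return ContrastResult(label=label, estimate=estimate, se=se, df=float(df), t=float(t), p=p)


def _group_blocks(X: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, gs = X[order], groups[order]
    boundaries = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1], True])
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        yield Xs[start:stop]


def _contrast_variance_and_df(
    X: np.ndarray,
    groups: np.ndarray,
    sigma_b2: float,
    sigma_e2: float,
    c: np.ndarray,
    residual_df: float,
    satterthwaite: bool = True,
) -> tuple[float, float]:
    """Variance of c'beta under V = sigma_e2 I + sigma_b2 ZZ', and its df.

    Works group-by-group (the random-effects design is a group indicator),
    so nothing larger than one group's block is ever materialised.  The
    Satterthwaite df uses the REML expected information of the two variance
    components.
    """
    p = X.shape[1]
    xtvix = np.zeros((p, p))
    g_e = np.zeros((p, p))  # X' V^-1 V^-1 X
    g_b = np.zeros((p, p))  # X' V^-1 Z Z' V^-1 X
    m_ee = np.zeros((p, p))
    m_eb = np.zeros((p, p))
    m_be = np.zeros((p, p))
    m_bb = np.zeros((p, p))
    t_ee = t_eb = t_bb = 0.0
    for Xg in _group_blocks(X, groups):
        n = Xg.shape[0]
        Vg = sigma_e2 * np.eye(n) + sigma_b2 * np.ones((n, n))
        Vi = np.linalg.inv(Vg)
        ViX = Vi @ Xg
        Vi1 = Vi.sum(axis=1)
        v = Xg.T @ Vi1  # X' V^-1 1
        w = ViX.T @ Vi1  # X' V^-1 V^-1 1
        xtvix += Xg.T @ ViX
        g_e += ViX.T @ ViX
        g_b += np.outer(v, v)
        m_ee += ViX.T @ Vi @ ViX
        m_eb += np.outer(w, v)
        m_be += np.outer(v, w)
        m_bb += float(Vi1.sum()) * np.outer(v, v)
        t_ee += float(np.trace(Vi @ Vi))
        t_eb += float(Vi1 @ Vi1)
        t_bb += float(Vi1.sum()) ** 2
    C = np.linalg.inv(xtvix)
    var = float(c @ C @ c)
    if not satterthwaite:
        return var, float(residual_df)

    grad = np.array([c @ C @ g_e @ C @ c, c @ C @ g_b @ C @ c])
    i_ee = 0.5 * (t_ee - 2.0 * np.trace(C @ m_ee) + np.trace(C @ g_e @ C @ g_e))
    i_eb = 0.5 * (
        t_eb - np.trace(C @ m_eb) - np.trace(C @ m_be) + np.trace(C @ g_e @ C @ g_b)
    )
    i_bb = 0.5 * (t_bb - 2.0 * np.trace(C @ m_bb) + np.trace(C @ g_b @ C @ g_b))
    info = np.array([[i_ee, i_eb], [i_eb, i_bb]])
    try:
        acov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return var, float(residual_df)
    denom = float(grad @ acov @ grad)
    if denom <= 0:
        return var, float(residual_df)
    df = 2.0 * var**2 / denom
    return var, float(min(df, residual_df * 10.0))


def _require_columns(trials: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in trials.columns]
    if missing:
        raise AnalysisError(f"trial table missing columns: {missing}")


def _fit_cell_means(
    trials: pd.DataFrame, factors: list[str], response: str = "cycles", group: str = "word"
) -> LMEFit:
    from statsmodels.regression.mixed_linear_model import MixedLM

    _require_columns(trials, [*factors, response, group])
    cells = sorted(map(tuple, trials[factors].drop_duplicates().itertuples(index=False)))
    key_of = {key: i for i, key in enumerate(cells)}
    idx = np.array([key_of[tuple(row)] for row in trials[factors].itertuples(index=False)])
    X = np.zeros((len(trials), len(cells)))
    X[np.arange(len(trials)), idx] = 1.0
    y = trials[response].to_numpy(dtype=float)
    groups = trials[group].to_numpy()

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
            beta = np.asarray(res.fe_params, dtype=float)
            sigma_b2 = float(np.asarray(res.cov_re)[0, 0])
            sigma_e2 = float(res.scale)
            converged = bool(getattr(res, "converged", True))
        except Exception:  # pragma: no cover - optimizer pathologies
            sigma_b2, converged = 0.0, False
            beta = None

    singular = (beta is None) or sigma_b2 <= 1e-8 * max(sigma_e2 if beta is not None else 1.0, 1e-12)
    if singular:
        if beta is None or sigma_b2 <= 0:
            logger.warning(
                "random-intercept variance singular; falling back to the "
                "zero-variance (OLS) fit"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - len(cells)
        sigma_e2 = float(resid @ resid / dof) if dof > 0 else float("nan")
        sigma_b2 = 0.0
    return LMEFit(
        cells=cells,
        beta=np.asarray(beta, dtype=float),
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        X=X,
        group_labels=groups,
        n_obs=len(y),
        factors=factors,
        singular=bool(singular),
        converged=converged,
    )


def fit_lme_2way(trials: pd.DataFrame) -> LMEFit:
    """cycles ~ SQ * WF + (1 | word) for one feedback x locus cell.

    Stimulus quality enters as a categorical factor with all its levels in
    one model (cell-means coding); contrasts are then built per pairing.
    """
    _require_columns(trials, ["band", "sq_percent", "cycles", "word"])
    for col in ("ia", "locus"):
        if col in trials.columns and trials[col].nunique() > 1:
            raise AnalysisError(
                f"2-way model expects trials from a single {col} cell; "
                f"got {sorted(trials[col].unique())}"
            )
    if trials["sq_percent"].nunique() < 2:
        raise AnalysisError("need at least two stimulus-quality levels")
    return _fit_cell_means(trials, ["band", "sq_percent"])


def planned_contrasts_2way(fit: LMEFit, low_sq: int) -> list[ContrastResult]:
    """The three planned contrasts for the 100% / ``low_sq`` pairing.

    Word frequency main effect (low minus high band, averaged over the two
    quality levels), the simple stimulus-quality effect for high-frequency
    words (degraded minus clear), and the SQ x WF interaction (difference
    of the bands' stimulus-quality effects).  Positive values mean slower
    low-frequency naming, slower degraded naming, and over-additivity.
    """
    if fit.factors != ["band", "sq_percent"]:
        raise AnalysisError("fit is not a band x sq_percent cell-means model")
    levels = {key[1] for key in fit.cells}
    if low_sq not in levels or 100 not in levels:
        raise AnalysisError(f"pairing 100/{low_sq} not present in fit (levels {sorted(levels)})")
    lo, hi = low_sq, 100
    wf = {("low", hi): 0.5, ("low", lo): 0.5, ("high", hi): -0.5, ("high", lo): -0.5}
    sq_hf = {("high", lo): 1.0, ("high", hi): -1.0}
    inter = {("low", lo): 1.0, ("low", hi): -1.0, ("high", lo): -1.0, ("high", hi): 1.0}
    return [
        fit.contrast(wf, f"word frequency (low SQ {lo}%)"),
        fit.contrast(sq_hf, f"stimulus quality, HF words (low SQ {lo}%)"),
        fit.contrast(inter, f"interaction SQ x WF (low SQ {lo}%)"),
    ]


def fit_lme_3way(
    trials: pd.DataFrame, low_sqs: Sequence[int] = (20, 40, 60, 80)
) -> tuple[LMEFit, list[ContrastResult]]:
    """cycles ~ SQ * WF * IA + (1 | word) pooled over feedback settings.

    Returns the fit plus the four three-way contrasts (one per pairing of
    the clear condition with a degraded level): the difference between the
    feedback-on and feedback-off SQ x WF interactions.  Lower-order terms
    are available from the fit itself but are not part of the report.
    """
    _require_columns(trials, ["band", "sq_percent", "ia", "cycles", "word"])
    if trials["ia"].nunique() < 2:
        raise AnalysisError("3-way model needs both feedback settings in the data")
    if "locus" in trials.columns and trials["locus"].nunique() > 1:
        raise AnalysisError("3-way model expects trials from a single locus")
    fit = _fit_cell_means(trials, ["band", "sq_percent", "ia"])
    results = []
    for lo in low_sqs:
        coeffs: dict[tuple, float] = {}
        for ia, sign in (("on", 1.0), ("off", -1.0)):
            coeffs[("low", lo, ia)] = sign
            coeffs[("low", 100, ia)] = -sign
            coeffs[("high", lo, ia)] = -sign
            coeffs[("high", 100, ia)] = sign
        results.append(fit.contrast(coeffs, f"SQ x WF x IA (low SQ {lo}%)"))
    return fit, results


# --------------------------------------------------------------------------
# Whole-table analysis (the reporting surface behind the CLI)
# --------------------------------------------------------------------------


def contrasts_to_frame(contrasts: Sequence[ContrastResult], **extra) -> pd.DataFrame:
    rows = []
    for cr in contrasts:
        row = dict(extra)
        row.update(
            contrast=cr.label, estimate=cr.estimate, se=cr.se, df=cr.df, t=cr.t, p=cr.p
        )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_trials(trials: pd.DataFrame, low_sqs: Sequence[int] = (20, 40, 60, 80)) -> dict:
    """Fit every per-cell 2-way model, both 3-way models, and summaries.

    Returns a dict with ``contrasts_2way``, ``contrasts_3way``,
    ``cell_means`` (mean cycles per condition cell) and ``wf_effects``
    (low- minus high-frequency mean cycles per stimulus-quality level, the
    frequency-effect-by-quality summary).
    """
    _require_columns(
        trials, ["word", "band", "ia", "locus", "sq_percent", "cycles"]
    )
    levels = sorted(trials["sq_percent"].unique())
    if len(levels) < 2:
        raise AnalysisError(
            "no 100%/degraded pairing possible: need the clear condition plus "
            f"at least one degraded level, got {levels}"
        )
    pairable = [lo for lo in low_sqs if lo in levels]
    if 100 not in levels or not pairable:
        raise AnalysisError("no 100%/degraded pairing possible in this table")

    two_way = []
    for (locus, ia), sub in trials.groupby(["locus", "ia"]):
        fit = fit_lme_2way(sub)
        for lo in pairable:
            two_way.append(
                contrasts_to_frame(
                    planned_contrasts_2way(fit, lo), locus=locus, ia=ia, low_sq=lo
                )
            )
    three_way = []
    for locus, sub in trials.groupby("locus"):
        _, contrasts = fit_lme_3way(sub, low_sqs=pairable)
        three_way.append(contrasts_to_frame(contrasts, locus=locus))

    cell_means = (
        trials.groupby(["locus", "ia", "sq_percent", "band"])["cycles"]
        .mean()
        .reset_index(name="mean_cycles")
    )
    wide = cell_means.pivot_table(
        index=["locus", "ia", "sq_percent"], columns="band", values="mean_cycles"
    ).reset_index()
    wide["wf_effect"] = wide["low"] - wide["high"]
    return {
        "contrasts_2way": pd.concat(two_way, ignore_index=True),
        "contrasts_3way": pd.concat(three_way, ignore_index=True),
        "cell_means": cell_means,
        "wf_effects": wide[["locus", "ia", "sq_percent", "wf_effect"]],
    }


def simulate_interaction_type1(
    reps: int = 1000,
    n_words_per_band: int = 30,
    sq_levels: Sequence[int] = (20, 40, 60, 80, 100),
    sigma_b: float = 8.0,
    sigma_e: float = 2.0,
    alpha: float = 0.05,
    low_sq: int = 20,
    seed: int = 0,
) -> float:
    """Type-I error of the interaction contrast under a true null.

    Generates balanced data with real word intercepts but no interaction,
    fits the 2-way model, and counts rejections of the ``100/low_sq``
    interaction contrast at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    words = [f"w{i:03d}" for i in range(2 * n_words_per_band)]
    bands = ["low"] * n_words_per_band + ["high"] * n_words_per_band
    base = pd.DataFrame(
        [
            {"word": w, "band": b, "sq_percent": s}
            for w, b in zip(words, bands)
            for s in sq_levels
        ]
    )
    sq_effect = {s: (100 - s) * 0.1 for s in sq_levels}
    band_effect = {"low": 5.0, "high": 0.0}
    fixed = (
        100.0
        + base["sq_percent"].map(sq_effect).to_numpy()
        + base["band"].map(band_effect).to_numpy()
    )
    rejections = 0
    for _ in range(reps):
        intercepts = dict(zip(words, rng.normal(0.0, sigma_b, size=len(words))))
        y = fixed + base["word"].map(intercepts).to_numpy()
        y = y + rng.normal(0.0, sigma_e, size=len(base))
        data = base.assign(cycles=y)
        fit = fit_lme_2way(data)
        inter = planned_contrasts_2way(fit, low_sq)[2]
        if inter.p < alpha:
            rejections += 1
    return rejections / reps
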