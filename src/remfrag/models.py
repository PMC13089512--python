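"""Linear mixed models with the planned-contrast scheme for condition effects.

Each outcome (valence, arousal, CDA.SCR, HRD, d') is modeled with fixed
factors Condition x Session x StimulusType (full factorial), a random
intercept per participant, and - for trial-level reactivity outcomes - a
crossed random intercept for the stimulus ID.  Omnibus effects are Wald
chi-square tests per term.  A significant Condition x Session interaction
is followed up by nine Bonferroni-adjusted planned comparisons: the three
session pairs within each condition (T0vT1, T0vT2, T1vT2) and the two
conditions at each session.  Interpretation is hierarchical: main effects
are subordinated to interactions involving the same factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

CONDITIONS = ("CTR", "FRG")
SESSIONS = ("T0", "T1", "T2")


@dataclass(frozen=True)
class LmmSpec:
    """Model specification for one outcome."""

    outcome: str
    #: crossed random intercept for the stimulus ID (trial-level reactivity)
    stimulus_random: bool = False
    participant_col: str = "subject"
    condition_col: str = "condition"
    session_col: str = "session"
    type_col: str = "stimulus_type"
    stimulus_col: str = "stimulus_id"


@dataclass(frozen=True)
class LmmResult:
    effects: pd.DataFrame          # term, statistic (Wald chi2), df, p
    contrasts: pd.DataFrame        # label, estimate, se, t, df, p_raw, p_bonferroni
    interaction_significant: bool
    interpretation: tuple[str, ...]
    converged: bool
    fallback_used: bool
    df_method: str = "residual"
    n_obs: int = 0


def _formula(spec: LmmSpec) -> str:
    return (f"{spec.outcome} ~ C({spec.condition_col}) * C({spec.session_col})"
            f" * C({spec.type_col})")


def _try_fit(model, require_converged: bool = False):
    """Attempt the fit across optimizers; return the best result or None."""
    last = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            res = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            continue
        if res.converged:
            return res
        last = res
    return None if require_converged else last


def _fit(data: pd.DataFrame, spec: LmmSpec):
    """Fit the mixed model; fall back to participant-only structure if needed."""
    fallback = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if spec.stimulus_random:
            model = MixedLM.from_formula(
                _formula(spec), data,
                groups=np.ones(len(data)),
                vc_formula={
                    "participant": f"0 + C({spec.participant_col})",
                    "stimulus": f"0 + C({spec.stimulus_col})",
                },
            )
            res = _try_fit(model, require_converged=True)
            if res is None:
                fallback = True
        if not spec.stimulus_random or fallback:
            model = MixedLM.from_formula(
                _formula(spec), data, groups=data[spec.participant_col],
            )
            res = _try_fit(model)
        if res is None:
            raise RuntimeError("mixed-model estimation failed for every optimizer")
    return model, res, fallback


def _cell_rows(model, spec: LmmSpec) -> dict[tuple[str, str], np.ndarray]:
    """Fixed-effects design rows of each Condition x Session cell mean.

    Each cell row averages the design rows over the stimulus-type levels
    (emmeans-style marginal means on a balanced reference grid).
    """
    import patsy

    design_info = model.data.design_info
    rows = {}
    for cond in CONDITIONS:
        for sess in SESSIONS:
            grid = pd.DataFrame({
                spec.condition_col: [cond, cond],
                spec.session_col: [sess, sess],
                spec.type_col: ["negative", "neutral"],
            })
            X = np.asarray(patsy.dmatrix(design_info, grid))
            rows[(cond, sess)] = X.mean(axis=0)
    return rows


PLANNED_PAIRS = (
    ("CTR: T0 vs T1", ("CTR", "T0"), ("CTR", "T1")),
    ("CTR: T0 vs T2", ("CTR", "T0"), ("CTR", "T2")),
    ("CTR: T1 vs T2", ("CTR", "T1"), ("CTR", "T2")),
    ("FRG: T0 vs T1", ("FRG", "T0"), ("FRG", "T1")),
    ("FRG: T0 vs T2", ("FRG", "T0"), ("FRG", "T2")),
    ("FRG: T1 vs T2", ("FRG", "T1"), ("FRG", "T2")),
    ("T0: CTR vs FRG", ("CTR", "T0"), ("FRG", "T0")),
    ("T1: CTR vs FRG", ("CTR", "T1"), ("FRG", "T1")),
    ("T2: CTR vs FRG", ("CTR", "T2"), ("FRG", "T2")),
)


def planned_contrasts(model, res, spec: LmmSpec, n_obs: int) -> pd.DataFrame:
    """The nine planned Condition/Session comparisons, Bonferroni-adjusted."""
    cells = _cell_rows(model, spec)
    k_fe = res.fe_params.shape[0]
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    fe = np.asarray(res.fe_params)
    df = max(n_obs - k_fe, 1)
    rows = []
    for label, a, b in PLANNED_PAIRS:
        L = cells[a] - cells[b]
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append({"label": label, "estimate": est, "se": se, "t": t,
                     "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def _interpretation(eff: pd.DataFrame, alpha: float) -> tuple[str, ...]:
    """Hierarchical reading: effects subordinated to higher-order interactions."""
    sig = {r["term"]: r["p"] < alpha for _, r in eff.iterrows() if np.isfinite(r["p"])}
    notes = []
    three = next((t for t in sig if t.count(":") == 2), None)
    if three and sig[three]:
        notes.append(f"interpret {three}; lower-order effects subordinated")
        return tuple(notes)
    for term, s in sig.items():
        if term.count(":") == 1 and s:
            notes.append(f"interpret {term}")
    if not notes:
        for term, s in sig.items():
            if term.count(":") == 0 and term != "Intercept" and s:
                notes.append(f"interpret main effect {term}")
    return tuple(notes) or ("no significant condition-related effects",)


def fit_and_contrast(
    data: pd.DataFrame, spec: LmmSpec, alpha: float = 0.05
) -> LmmResult:
    """Fit the factorial mixed model and run the planned-comparison scheme.

    The nine planned contrasts are computed whenever the Condition x Session
    interaction term is estimable; ``interaction_significant`` gates their
    interpretation per the hierarchical reporting rule.
    """
    needed = {spec.outcome, spec.participant_col, spec.condition_col,
              spec.session_col, spec.type_col}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for col in (spec.condition_col, spec.session_col, spec.type_col):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 levels")
    data = data.dropna(subset=[spec.outcome]).copy()

    model, res, fallback = _fit(data, spec)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test_terms(scalar=True)
    eff = wt.table.reset_index().rename(
        columns={"index": "term", "statistic": "statistic", "pvalue": "p",
                 "df_constraint": "df"})
    eff = eff[eff["term"] != "Intercept"].reset_index(drop=True)

    cs_term = next((t for t in eff["term"]
                    if t.count(":") == 1 and "condition" in t and "session" in t), None)
    inter_sig = bool(
        cs_term is not None
        and np.isfinite(eff.set_index("term").at[cs_term, "p"])
        and eff.set_index("term").at[cs_term, "p"] < alpha
    )
    contrasts = planned_contrasts(model, res, spec, n_obs=len(data))
    return LmmResult(
        effects=eff, contrasts=contrasts, interaction_significant=inter_sig,
        interpretation=_interpretation(eff, alpha),
        converged=bool(res.converged), fallback_used=fallback, n_obs=len(data),
    )
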