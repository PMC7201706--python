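"""Conditional logistic regression for 1:M matched sets with one binary
exposure, fitted by maximum conditional likelihood.

The model: within a matched set of one case and m controls sharing an index
date, the probability that the case (rather than any particular control) is
the diseased member, given the set's exposures x_1..x_{m+1}, is

    P(case | set) = exp(beta * x_case) / sum_j exp(beta * x_j).

Conditioning on set membership eliminates the per-set (age/sex/practice)
nuisance intercepts; exp(beta) is the exposure odds ratio.  Because the
exposure is binary and members are exchangeable, each set is summarised by
its size, its total number of exposed members t, and whether the case is
exposed: the denominator is ``t e^beta + (size - t)``.  Fully concordant
sets (t = 0 or t = size) contribute an exact constant, so the implemented
function is a true log-likelihood.

The MLE is found by Newton-Raphson from beta = 0 with step-halving (the
1-D problem is strictly concave on the informative sets).  The estimate is
infinite — and reported as non-estimable, the analogue of a "-" table
cell — when every informative set has the case exposed, or none does
(separation).  Standard errors come from the observed information at the
MLE and confidence intervals are Wald on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class ExposureSet:
    """One matched set reduced to its exposure pattern."""

    set_id: str
    case_exposed: bool
    controls_exposed: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.controls_exposed) < 1:
            raise ValueError("a matched set needs at least one control")


class ConditionalLogit:
    """Single-covariate conditional logistic model on matched sets.

    Parameters
    ----------
    sets:
        Iterable of :class:`ExposureSet` (or (case_exposed,
        controls_exposed) pairs).
    """

    def __init__(self, sets):
        sets = list(sets)
        if not sets:
            raise ValueError("no matched sets supplied")
        self.sets: list[ExposureSet] = [
            s if isinstance(s, ExposureSet) else ExposureSet(str(i), s[0], tuple(s[1]))
            for i, s in enumerate(sets)
        ]
        self.x = np.array([int(s.case_exposed) for s in self.sets])
        self.t_ctrl = np.array([sum(map(int, s.controls_exposed)) for s in self.sets])
        self.m = np.array([len(s.controls_exposed) for s in self.sets])
        self.size = self.m + 1
        self.t = self.x + self.t_ctrl

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, set_col: str = "set_id",
                       case_col: str = "is_case",
                       exposure_col: str = "exposed") -> "ConditionalLogit":
        """Build from a long frame with one row per set member."""
        sets = []
        for sid, grp in df.groupby(set_col, sort=True):
            cases = grp[grp[case_col].astype(bool)]
            controls = grp[~grp[case_col].astype(bool)]
            if len(cases) != 1:
                raise ValueError(f"set {sid!r} has {len(cases)} cases; expected 1")
            sets.append(ExposureSet(
                str(sid), bool(cases[exposure_col].iloc[0]),
                tuple(controls[exposure_col].astype(bool)),
            ))
        return cls(sets)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, beta):
        """Conditional log-likelihood; accepts scalar or array beta."""
        beta = np.asarray(beta, dtype=float)
        b = beta[..., None]
        t = self.t.astype(float)
        u = (self.size - self.t).astype(float)
        with np.errstate(divide="ignore"):
            log_t, log_u = np.log(t), np.log(u)
        denom = np.logaddexp(log_t + b, np.broadcast_to(log_u, b.shape[:-1] + log_u.shape))
        ll = (b * self.x - denom).sum(axis=-1)
        return ll if ll.ndim else float(ll)

    def score(self, beta: float) -> float:
        t = self.t.astype(float)
        u = (self.size - self.t).astype(float)
        te = t * np.exp(beta)
        p = te / (te + u)
        return float((self.x - p).sum())

    def information(self, beta: float) -> float:
        t = self.t.astype(float)
        u = (self.size - self.t).astype(float)
        te = t * np.exp(beta)
        p = te / (te + u)
        return float((p * (1.0 - p)).sum())

    # -- estimability -------------------------------------------------------

    @property
    def informative(self) -> np.ndarray:
        """Sets whose members are not all concordant in exposure."""
        return (self.t > 0) & (self.t < self.size)

    @property
    def separated(self) -> bool:
        """True when the conditional MLE is infinite (or undefined)."""
        inf = self.informative
        n_inf = int(inf.sum())
        if n_inf == 0:
            return True
        tcase = int(self.x[inf].sum())
        return tcase == 0 or tcase == n_inf

    def _canonical_flip(self) -> bool:
        """Fit the orientation whose informative sets have the
        lexicographically smaller encoding, so that complementing every
        exposure negates beta exactly.  Concordant sets are ignored: they
        carry no information and must not perturb the estimate."""
        inf = self.informative
        size, t, x = self.size[inf], self.t[inf], self.x[inf]
        key = sorted(zip(size.tolist(), t.tolist(), x.tolist()))
        key_f = sorted(zip(size.tolist(), (size - t).tolist(), (1 - x).tolist()))
        return key_f < key

    # -- fitting ------------------------------------------------------------

    def fit(self, tol_score: float = 1e-8, tol_step: float = 1e-10,
            maxiter: int = 100,
            min_exposed_for_report: int = 5) -> "ConditionalLogitResults":
        """Maximise the conditional likelihood.

        Returns a results object; when the data are separated the result is
        flagged non-estimable and carries no point estimate.
        ``min_exposed_for_report`` sets the sparse-cell suppression
        threshold used by the reporting layer (a presentation convention,
        not part of the estimate).
        """
        counts = dict(
            n_sets=len(self.sets),
            n_cases=len(self.sets),
            n_controls=int(self.m.sum()),
            n_exposed_cases=int(self.x.sum()),
            n_exposed_controls=int(self.t_ctrl.sum()),
            n_informative_sets=int(self.informative.sum()),
        )
        if self.separated:
            return ConditionalLogitResults(
                model=self, beta=np.nan, se=np.nan, estimable=False,
                converged=False, n_iter=0,
                min_exposed_for_report=min_exposed_for_report, **counts)

        if self._canonical_flip():
            flipped = ConditionalLogit([
                ExposureSet(s.set_id, not s.case_exposed,
                            tuple(not c for c in s.controls_exposed))
                for s in self.sets
            ])
            res = flipped.fit(tol_score, tol_step, maxiter, min_exposed_for_report)
            return ConditionalLogitResults(
                model=self, beta=-res.beta, se=res.se, estimable=True,
                converged=res.converged, n_iter=res.n_iter,
                min_exposed_for_report=min_exposed_for_report, **counts)

        # Newton on the informative sets only: concordant sets contribute an
        # exact constant to the log-likelihood and zero score/information,
        # so they must not perturb the iteration path at all
        inf = self.informative
        t = self.t[inf].astype(float)
        u = (self.size[inf] - self.t[inf]).astype(float)
        x = self.x[inf].astype(float)

        def _ll(b: float) -> float:
            return float((b * x - np.log(t * np.exp(b) + u)).sum())

        def _score_info(b: float) -> tuple[float, float]:
            p = t * np.exp(b) / (t * np.exp(b) + u)
            return float((x - p).sum()), float((p * (1.0 - p)).sum())

        beta = 0.0
        ll = _ll(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            s, info = _score_info(beta)
            if abs(s) < tol_score:
                converged = True
                break
            step = s / info
            # step-halving: the 1-D likelihood is concave, so a short enough
            # Newton step always improves it
            new_beta, new_ll = beta + step, _ll(beta + step)
            while new_ll < ll and abs(step) > tol_step:
                step *= 0.5
                new_beta, new_ll = beta + step, _ll(beta + step)
            if abs(new_beta - beta) < tol_step:
                beta, ll = new_beta, new_ll
                converged = True
                break
            beta, ll = new_beta, new_ll
        if not converged and abs(_score_info(beta)[0]) >= tol_score:
            raise EstimationError(
                f"Newton-Raphson failed to converge in {maxiter} iterations "
                f"(beta={beta:.6g}, score={_score_info(beta)[0]:.3g})")
        se = 1.0 / np.sqrt(_score_info(beta)[1])
        return ConditionalLogitResults(
            model=self, beta=float(beta), se=float(se), estimable=True,
            converged=True, n_iter=it,
            min_exposed_for_report=min_exposed_for_report, **counts)


@dataclass
class ConditionalLogitResults:
    """Fitted conditional-logit estimate for one binary feature."""

    model: ConditionalLogit
    beta: float
    se: float
    estimable: bool
    converged: bool
    n_iter: int
    n_sets: int
    n_cases: int
    n_controls: int
    n_exposed_cases: int
    n_exposed_controls: int
    n_informative_sets: int
    min_exposed_for_report: int = 5

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta)) if self.estimable else np.nan

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval for the odds ratio."""
        if not self.estimable:
            return (np.nan, np.nan)
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return (float(np.exp(self.beta - z * self.se)),
                float(np.exp(self.beta + z * self.se)))

    @property
    def ci95(self) -> tuple[float, float]:
        if not self.estimable:
            return (np.nan, np.nan)
        return (float(np.exp(self.beta - Z95 * self.se)),
                float(np.exp(self.beta + Z95 * self.se)))

    @property
    def suppressed(self) -> bool:
        """Whether the reporting layer should print "-" for this estimate:
        non-estimable, or fewer exposed subjects than the sparse-cell
        threshold."""
        total_exposed = self.n_exposed_cases + self.n_exposed_controls
        return (not self.estimable) or total_exposed < self.min_exposed_for_report

    def summary(self) -> str:
        lines = [
            "Conditional logistic regression (1 case : M controls, single binary exposure)",
            "=" * 78,
            f"Matched sets: {self.n_sets}   informative: {self.n_informative_sets}"
            f"   controls: {self.n_controls}",
            f"Exposed cases: {self.n_exposed_cases}/{self.n_cases}"
            f"   exposed controls: {self.n_exposed_controls}/{self.n_controls}",
        ]
        if self.estimable:
            lo, hi = self.ci95
            lines += [
                f"log OR (beta): {self.beta: .4f}   SE: {self.se:.4f}"
                f"   iterations: {self.n_iter}",
                f"OR: {self.or_point:.3f}   95% CI: ({lo:.3f}, {hi:.3f})",
            ]
        else:
            lines.append("Non-estimable: exposure separated across informative sets "
                         "(likelihood maximised at infinite beta)")
        if self.suppressed:
            lines.append(f"[suppressed in tables: exposed total < "
                         f"{self.min_exposed_for_report} or non-estimable]")
        lines.append("=" * 78)
        return "\n".join(lines)


def fit_feature(matrix: pd.DataFrame, feature: str, comparison: str,
                horizon: str,
                min_exposed_for_report: int = 5) -> ConditionalLogitResults | None:
    """Fit one feature at one horizon for one comparison group.

    Applies the horizon eligibility rules: a set is dropped whole when its
    case is ineligible; ineligible controls are dropped individually; sets
    left without controls are dropped.  Returns None when no sets survive.
    """
    sub = matrix[(matrix["comparison"] == comparison)
                 & (matrix["horizon"] == horizon)]
    sets: list[ExposureSet] = []
    for sid, grp in sub.groupby("set_id", sort=True):
        case = grp[grp["role"] == "case"]
        ctrl = grp[(grp["role"] == "control") & grp["eligible"]]
        if len(case) != 1 or not bool(case["eligible"].iloc[0]) or len(ctrl) == 0:
            continue
        sets.append(ExposureSet(str(sid), bool(case[feature].iloc[0]),
                                tuple(ctrl[feature].astype(bool))))
    if not sets:
        return None
    return ConditionalLogit(sets).fit(
        min_exposed_for_report=min_exposed_for_report)


def fit_all(matrix: pd.DataFrame, comparison: str, horizon: str,
            features: list[str] | None = None,
            min_exposed_for_report: int = 5) -> pd.DataFrame:
    """One fitted row per feature at a horizon/comparison.

    Columns follow the results-table convention: counts, percentages, OR
    with 95% CI, estimability and suppression flags.
    """
    if features is None:
        reserved = {"comparison", "set_id", "patient_id", "role", "horizon",
                    "eligible"}
        features = [c for c in matrix.columns if c not in reserved]
    rows = []
    for feat in features:
        res = fit_feature(matrix, feat, comparison, horizon,
                          min_exposed_for_report)
        if res is None:
            rows.append({"comparison": comparison, "horizon": horizon,
                         "feature": feat, "n_cases": 0, "n_controls": 0,
                         "n_exposed_cases": 0, "pct_cases": np.nan,
                         "n_exposed_controls": 0, "pct_controls": np.nan,
                         "beta": np.nan, "se": np.nan, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "estimable": False, "suppressed": True,
                         "n_informative_sets": 0})
            continue
        lo, hi = res.ci95
        rows.append({
            "comparison": comparison, "horizon": horizon, "feature": feat,
            "n_cases": res.n_cases, "n_controls": res.n_controls,
            "n_exposed_cases": res.n_exposed_cases,
            "pct_cases": 100.0 * res.n_exposed_cases / res.n_cases,
            "n_exposed_controls": res.n_exposed_controls,
            "pct_controls": 100.0 * res.n_exposed_controls / res.n_controls,
            "beta": res.beta, "se": res.se, "or": res.or_point,
            "ci_low": lo, "ci_high": hi, "estimable": res.estimable,
            "suppressed": res.suppressed,
            "n_informative_sets": res.n_informative_sets,
        })
    return pd.DataFrame(rows)
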