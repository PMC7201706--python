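"""Result assembly: OR tables, first-occurrence lead-time summaries and
OR-versus-gap trend series.

Tables mirror the conventional case-control layout — per feature the number
and percentage exposed among cases and controls plus OR (95% CI) — with "-"
in the OR cells for suppressed estimates (non-estimable, or below the
sparse-cell threshold).  Trend series carry non-estimable points with a
flag rather than dropping them.  Figures are emitted as tidy CSV series
(plus optional matplotlib plots); the CSV is the canonical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AssemblyError
from .features import DEFAULT_GAPS
from .records import RecordSet

DAYS_PER_YEAR = 365.25


@dataclass
class LeadTimeSummary:
    """Years from first coded occurrence of a category to the index date,
    over cases with at least one occurrence."""

    category: str
    n: int
    years: np.ndarray          # unfloored, one value per contributing case
    median: float
    q1: float
    q3: float
    hist_counts: np.ndarray    # 1-year left-closed integer bins
    hist_edges: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "years_before_index": self.hist_edges[:-1].astype(int),
            "n_cases": self.hist_counts.astype(int),
        })


def lead_time_summary(rs: RecordSet, cohort: pd.DataFrame,
                      category: str) -> LeadTimeSummary:
    """First-occurrence lead time for cases (deduplicated across
    comparisons).  Cases with no occurrence on/before their index date do
    not contribute; an empty summary is valid."""
    cases = cohort[cohort["role"] == "case"][
        ["patient_id", "index_date"]].drop_duplicates("patient_id")
    ev = rs.events[rs.events["category"] == category]
    first = ev.groupby("patient_id")["date"].min()
    years = []
    for row in cases.itertuples(index=False):
        f = first.get(row.patient_id, pd.NaT)
        if pd.isna(f) or f > row.index_date:
            continue
        years.append((row.index_date - f).days / DAYS_PER_YEAR)
    years = np.asarray(sorted(years), dtype=float)
    if years.size:
        med, q1, q3 = (float(np.percentile(years, q)) for q in (50, 25, 75))
        top = int(np.floor(years.max())) + 1
        counts, edges = np.histogram(np.floor(years), bins=np.arange(top + 1))
    else:
        med = q1 = q3 = float("nan")
        counts, edges = np.zeros(0), np.arange(1)
    return LeadTimeSummary(category, int(years.size), years, med, q1, q3,
                           counts, edges)


@dataclass
class TimeTrendSeries:
    """OR at each window gap for one feature and comparison group."""

    feature: str
    comparison: str
    points: pd.DataFrame  # gap_months, or, ci_low, ci_high, estimable

    def to_frame(self) -> pd.DataFrame:
        out = self.points.copy()
        out.insert(0, "comparison", self.comparison)
        out.insert(0, "feature", self.feature)
        return out


def time_trend(results: pd.DataFrame, feature: str, comparison: str,
               gaps: tuple[int, ...] = DEFAULT_GAPS) -> TimeTrendSeries:
    """Assemble the OR-versus-gap series from fitted results.

    Raises :class:`AssemblyError` naming the first missing gap or the
    feature if absent; non-estimable points are kept, flagged.
    """
    sub = results[(results["feature"] == feature)
                  & (results["comparison"] == comparison)]
    if sub.empty:
        raise AssemblyError(
            f"feature {feature!r} absent from results for {comparison!r}")
    rows = []
    for gap in sorted(gaps):
        hz = f"gap_{gap}"
        hit = sub[sub["horizon"] == hz]
        if hit.empty:
            raise AssemblyError(f"missing horizon gap_{gap} for {feature!r}")
        r = hit.iloc[0]
        rows.append({"gap_months": gap, "or": r["or"], "ci_low": r["ci_low"],
                     "ci_high": r["ci_high"], "estimable": bool(r["estimable"])})
    return TimeTrendSeries(feature, comparison, pd.DataFrame(rows))


# -- tables -----------------------------------------------------------------

def _fmt_or(v: float) -> str:
    if not np.isfinite(v):
        return "-"
    return f"{v:.2f}" if v < 1 else f"{v:.1f}"


def _fmt_pct(v: float) -> str:
    return "-" if not np.isfinite(v) else f"{v:.1f}"


def format_table(results: pd.DataFrame) -> pd.DataFrame:
    """Human-readable table cells from one (comparison, horizon) slice of
    fitted results; percentages are 100*n/N to 1 decimal, suppressed OR/CI
    cells print "-"."""
    rows = []
    for _, r in results.iterrows():
        supp = bool(r["suppressed"])
        rows.append({
            "feature": r["feature"],
            "cases_n": int(r["n_exposed_cases"]),
            "cases_pct": _fmt_pct(r["pct_cases"]),
            "controls_n": int(r["n_exposed_controls"]),
            "controls_pct": _fmt_pct(r["pct_controls"]),
            "or": "-" if supp else _fmt_or(r["or"]),
            "ci95": "-" if supp else f"({_fmt_or(r['ci_low'])}, {_fmt_or(r['ci_high'])})",
        })
    return pd.DataFrame(rows, columns=["feature", "cases_n", "cases_pct",
                                       "controls_n", "controls_pct", "or", "ci95"])


def render_tables(results: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one formatted CSV (plus a plain-text preview) per
    (comparison, horizon) present in the results.  Pure function of the
    results frame: regenerating from the same results is byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    keys = results[["comparison", "horizon"]].drop_duplicates() \
        .sort_values(["comparison", "horizon"])
    for comparison, horizon in keys.itertuples(index=False):
        sub = results[(results["comparison"] == comparison)
                      & (results["horizon"] == horizon)]
        table = format_table(sub)
        stem = f"table_{comparison}_{horizon}"
        csv_path = out_dir / f"{stem}.csv"
        table.to_csv(csv_path, index=False)
        txt_path = out_dir / f"{stem}.txt"
        txt_path.write_text(table.to_string(index=False) + "\n")
        written += [csv_path, txt_path]
    return written


def write_lead_time(summary: LeadTimeSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, index=False)


def write_trend(series: TimeTrendSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


# -- optional plots ---------------------------------------------------------

def plot_trend(series_list: list[TimeTrendSeries], path: str | Path,
               title: str | None = None) -> None:
    """OR-versus-gap plot (log OR scale), one line per series; dotted 95%
    CI bounds, mirroring the conventional presentation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"population": "tab:blue", "symptomatic": "tab:red"}
    for s in series_list:
        pts = s.points[s.points["estimable"]]
        c = colors.get(s.comparison, None)
        ax.plot(pts["gap_months"], pts["or"], "o-", color=c,
                label=f"{s.feature} vs {s.comparison}")
        ax.plot(pts["gap_months"], pts["ci_low"], ":", color=c)
        ax.plot(pts["gap_months"], pts["ci_high"], ":", color=c)
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_yscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("gap between window end and index date (months)")
    ax.set_ylabel("odds ratio (log scale)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lead_time(summary: LeadTimeSummary, path: str | Path) -> None:
    """Histogram of whole years between first occurrence and index date."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(summary.hist_edges[:-1], summary.hist_counts, width=0.9,
           align="edge", color="tab:blue")
    ax.set_xlabel(f"years before index date ({summary.category} first coded)")
    ax.set_ylabel("cases")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
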