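"""Statistical layer on fitted parameters.

Three tests mirror the downstream analysis of the fitted plate:

* two-way ANOVA of a fitted parameter on two binary environmental factors
  (CAF presence × drug presence), with Type II sums of squares so that
  unbalanced designs are handled and balanced ones reduce to the classical
  decomposition;
* a paired t-test comparing the two competition coefficients within wells;
* an ANCOVA probing density-dependence nonlinearity: per-capita growth
  (centered log-differences on the 4 h grid) regressed on population size
  and its square — logistic growth predicts a vanishing quadratic term,
  Gompertz and von Bertalanffy a positive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .plates import WellRecord

__all__ = ["TermResult", "TestReport", "two_way_anova", "paired_t", "ancova_percapita",
           "reports_to_frame"]


@dataclass(frozen=True)
class TermResult:
    """One tested term: statistic, degrees of freedom, p-value."""

    term: str
    stat: float
    df1: int
    df2: int | None
    p: float


@dataclass
class TestReport:
    """A named test with its per-term statistics and a direction summary."""

    test: str
    terms: list[TermResult] = field(default_factory=list)
    direction: str = ""
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def reports_to_frame(reports: Iterable[TestReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for t in r.terms:
            rows.append(
                {"test": r.test, "term": t.term, "stat": t.stat,
                 "df1": t.df1, "df2": t.df2, "p": t.p}
            )
    return pd.DataFrame(rows, columns=["test", "term", "stat", "df1", "df2", "p"])


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("A", "B"),
    test_name: str = "two_way_anova",
) -> TestReport:
    """Two-way ANOVA of ``values`` on two binary factors plus interaction.

    Type II sums of squares (each main effect adjusted for the other; the
    interaction tested last), which coincide with the classical balanced
    decomposition when the design is balanced.  If any design cell is empty
    the interaction is dropped with a warning and an additive model is fit.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal lengths")
    if len(np.unique(a)) != 2 or len(np.unique(b)) != 2:
        raise ValueError("both factors must be binary")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")

    report = TestReport(test=test_name)
    n = len(y)
    if np.ptp(y) == 0.0:
        # no variance at all: every F statistic is 0 by convention
        for term, d in ((names[0], 1), (names[1], 1), (f"{names[0]}:{names[1]}", 1)):
            report.terms.append(TermResult(term, 0.0, d, n - 4, 1.0))
        report.notes.append("zero variance in response")
        return report

    df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
    cells = df.groupby(["A", "B"]).size()
    full_cells = len(cells) == 4 and (cells >= 1).all()
    interaction_ok = len(cells) == 4 and (cells >= 2).all()
    if not interaction_ok:
        warnings.warn("empty or singleton design cell: interaction term dropped",
                      UserWarning)
        formula = "y ~ C(A) + C(B)"
    else:
        formula = "y ~ C(A) * C(B)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)

    label_map = {"C(A)": names[0], "C(B)": names[1],
                 "C(A):C(B)": f"{names[0]}:{names[1]}"}
    df_resid = int(table.loc["Residual", "df"])
    for row, label in label_map.items():
        if row not in table.index:
            continue
        report.terms.append(
            TermResult(
                term=label,
                stat=float(table.loc[row, "F"]),
                df1=int(table.loc[row, "df"]),
                df2=df_resid,
                p=float(table.loc[row, "PR(>F)"]),
            )
        )
    means = df.groupby("A")["y"].mean()
    report.direction = " ; ".join(f"{names[0]}={k}: mean {v:.4g}" for k, v in means.items())
    return report


def paired_t(values_a: Sequence[float], values_b: Sequence[float],
             test_name: str = "paired_t") -> TestReport:
    """Paired t-test on per-well differences; df = n - 1, two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    report = TestReport(test=test_name)
    report.terms.append(TermResult("difference", float(t), 1, n - 1, float(p)))
    report.direction = f"mean difference {float(np.mean(diff)):.4g}"
    return report


def _percapita_points(well: WellRecord, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Centered log-difference growth-rate estimates paired with population size.

    r_i = (ln N_{i+1} - ln N_{i-1}) / (t_{i+1} - t_{i-1}) at interior grid
    points; points whose stencil touches a nonpositive population are dropped.
    """
    t = well.times
    N = well.channel(channel)
    rs, Ns = [], []
    for i in range(1, len(t) - 1):
        if N[i - 1] > 0 and N[i] > 0 and N[i + 1] > 0:
            rs.append((np.log(N[i + 1]) - np.log(N[i - 1])) / (t[i + 1] - t[i - 1]))
            Ns.append(N[i])
    return np.asarray(Ns), np.asarray(rs)


def ancova_percapita(
    wells: Sequence[WellRecord],
) -> dict[tuple[str, str], TestReport]:
    """Test density-dependence nonlinearity per (environment × cell type).

    Pools replicate drug-free monoculture wells, estimates per-capita growth
    by centered log-differences, and regresses it on population size and
    size squared.  The report carries the linear and quadratic terms with
    t statistics; a significant positive quadratic term is the Gompertz /
    von Bertalanffy signature, while logistic growth predicts a purely
    linear decline.
    """
    groups: dict[tuple[str, str], list[WellRecord]] = {}
    for w in wells:
        if w.drug:
            raise ValueError("ANCOVA applies to drug-free monoculture wells")
        if w.seeding_ratio == 1.0:
            ch = "sensitive"
        elif w.seeding_ratio == 0.0:
            ch = "resistant"
        else:
            raise ValueError(f"well {w.well_id} is not a monoculture")
        if len(w.times) < 3:
            raise ValueError("need at least 3 time points per well")
        groups.setdefault((w.environment, ch), []).append(w)

    out: dict[tuple[str, str], TestReport] = {}
    for key, ws in groups.items():
        Ns, rs = [], []
        for w in ws:
            n, r = _percapita_points(w, key[1])
            Ns.append(n)
            rs.append(r)
        N = np.concatenate(Ns)
        r = np.concatenate(rs)
        name = f"ancova_percapita[{key[0]},{key[1]}]"
        if len(N) == 0:
            raise ValueError(f"all growth-rate points dropped for {key}")
        report = TestReport(test=name)
        if np.ptp(N) == 0.0 or len(N) < 4:
            # constant population (or too few points): slopes are zero by
            # construction and the quadratic term cannot be estimated
            report.terms.append(TermResult("N", 0.0, 1, max(len(N) - 1, 1), 1.0))
            report.terms.append(TermResult("N2", 0.0, 1, max(len(N) - 1, 1), 1.0))
            report.notes.append("degenerate design: constant population")
            out[key] = report
            continue
        df = pd.DataFrame({"r": r, "N": N, "N2": N**2})
        fit = smf.ols("r ~ N + N2", data=df).fit()
        df_resid = int(fit.df_resid)
        for term in ("N", "N2"):
            report.terms.append(
                TermResult(term, float(fit.tvalues[term]), 1, df_resid,
                           float(fit.pvalues[term]))
            )
        report.direction = (
            f"linear slope {fit.params['N']:.3e}; quadratic {fit.params['N2']:.3e} "
            f"({'significant' if fit.pvalues['N2'] < 0.05 else 'n.s.'} at 0.05)"
        )
        out[key] = report
    return out
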