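"""Inter-rater agreement statistics: Cohen's kappa and Spearman's rho.

These are the statistics used to validate a semi-automatic scorer against a
human rater: chance-corrected categorical agreement (kappa, with the
asymptotic 95% CI of Fleiss, Cohen & Everitt) and rank correlation for
ordinal scores (Spearman's rho, tie-aware via mid-ranks, with a Fisher-z
confidence interval and a t-approximation p-value).  Kappa magnitudes are
verbalized on the Landis & Koch scale ("slight" ... "almost perfect").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Landis & Koch verbal bands: (upper bound, label); bounds are inclusive.
LANDIS_KOCH_BANDS = [
    (0.0, "poor"),          # below 0 (exclusive at 0 handled explicitly)
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


class DegenerateInputError(ValueError):
    """The statistic is undefined for this input (zero variance / p_e = 1)."""


@dataclass
class PairedScores:
    """Paired ratings of the same items by two raters.

    ``items`` is a list of ``(item_id, rating_a, rating_b)``; pairs with a
    missing rating (None/NaN) are dropped and counted in ``n_dropped``.
    """

    items: list[tuple]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        kept = []
        dropped = 0
        for it in self.items:
            _, a, b = it
            if a is None or b is None or (isinstance(a, float) and np.isnan(a)) \
                    or (isinstance(b, float) and np.isnan(b)):
                dropped += 1
            else:
                kept.append(it)
        self.items = kept
        self.n_dropped += dropped
        if len(self.items) < 2:
            raise ValueError("need at least 2 complete pairs")

    @property
    def a(self) -> list:
        return [it[1] for it in self.items]

    @property
    def b(self) -> list:
        return [it[2] for it in self.items]

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class AgreementResult:
    """Agreement panel for one pair of raters (kappa + rho + verbal band)."""

    n: int
    kappa: float
    kappa_ci95: tuple[float, float]
    rho: float
    rho_ci95: tuple[float, float]
    rho_p: float
    df: int
    interpretation: str

    def summary(self) -> str:
        k_lo, k_hi = self.kappa_ci95
        r_lo, r_hi = self.rho_ci95
        return (
            f"n = {self.n}\n"
            f"Cohen's kappa = {self.kappa:.3f} "
            f"(95% CI {k_lo:.3f}-{k_hi:.3f}) — {self.interpretation}\n"
            f"Spearman's rho = {self.rho:.3f} "
            f"(df = {self.df}, 95% CI {r_lo:.3f}-{r_hi:.3f}, p = {self.rho_p:.4g})"
        )


def crosstab(pairs: PairedScores) -> pd.DataFrame:
    """Square contingency table over the union of observed categories.

    Rows are rater A, columns rater B, in sorted category order; the cell
    sum equals the number of pairs.
    """
    a, b = pairs.a, pairs.b
    cats = sorted(set(a) | set(b), key=str)
    tab = pd.crosstab(pd.Categorical(a, categories=cats),
                      pd.Categorical(b, categories=cats), dropna=False)
    tab = tab.reindex(index=cats, columns=cats, fill_value=0)
    tab.index.name, tab.columns.name = "rater_a", "rater_b"
    return tab


def cohens_kappa(table) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa with an asymptotic 95% CI from a contingency table.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed diagonal
    proportion and ``p_e`` the chance agreement expected from the marginals.
    The standard error uses the large-sample variance of Fleiss, Cohen &
    Everitt (1969); the interval ``kappa ± 1.96 SE`` is clamped to [-1, 1].
    Categories absent from both raters are dropped first.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    keep = (t.sum(axis=0) + t.sum(axis=1)) > 0
    t = t[np.ix_(keep, keep)]
    n = t.sum()
    if n < 2:
        raise ValueError("need at least 2 rated items")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = np.trace(p)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateInputError("p_e = 1: kappa undefined (single category)")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt asymptotic variance
    k = t.shape[0]
    a_term = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(k)
    )
    b_term = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(k) for j in range(k) if i != j
    )
    c_term = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (a_term + b_term - c_term) / (n * (1.0 - p_e) ** 2)
    se = np.sqrt(max(var, 0.0))
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return float(kappa), (float(lo), float(hi))


def spearman_rho(pairs: PairedScores) -> tuple[float, tuple[float, float], float, int]:
    """Spearman rank correlation with Fisher-z CI and t-approximation p.

    rho is the Pearson correlation of mid-ranks (tie-aware).  The 95% CI
    uses the Fisher z-transform with ``SE = 1/sqrt(n-3)``; the p-value comes
    from ``t = rho*sqrt((n-2)/(1-rho^2))`` on ``df = n-2`` degrees of
    freedom (two-sided).
    """
    x = np.asarray(pairs.a, dtype=float)
    y = np.asarray(pairs.b, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("zero rank variance: rho undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))

    df = n - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)

    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        half = 1.96 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (-1.0, 1.0) if abs(rho) < 1.0 else (rho, rho)
    return rho, ci, p, df


def interpret_kappa(kappa: float) -> str:
    """Verbalize a kappa on the Landis & Koch scale."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.0:
        return "poor"
    for hi, label in LANDIS_KOCH_BANDS[1:]:
        if kappa <= hi:
            return label
    return "almost perfect"


def agreement(pairs: PairedScores) -> AgreementResult:
    """Full agreement panel: kappa (on the crosstab), rho (on ranks), band.

    Non-numeric ratings are mapped to integer codes in sorted category order
    before ranking, which treats the categories as ordinal on that order.
    """
    kappa, kci = cohens_kappa(crosstab(pairs).to_numpy())
    try:
        numeric = PairedScores(
            [(i, float(a), float(b)) for (i, a, b) in pairs.items]
        )
    except (TypeError, ValueError):
        numeric = _categorical_to_codes(pairs)
    rho, rci, p, df = spearman_rho(numeric)
    return AgreementResult(
        n=len(pairs), kappa=kappa, kappa_ci95=kci,
        rho=rho, rho_ci95=rci, rho_p=p, df=df,
        interpretation=interpret_kappa(kappa),
    )


def _categorical_to_codes(pairs: PairedScores) -> PairedScores:
    cats = sorted(set(pairs.a) | set(pairs.b), key=str)
    code = {c: i for i, c in enumerate(cats)}
    return PairedScores(
        [(i, code[a], code[b]) for (i, a, b) in pairs.items]
    )
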