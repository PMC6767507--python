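"""Agreement between predicted and published Red List categories.

Categories are compared on an ordinal scale — LC and NT are pooled at 0
(the predictor never emits NT), then VU = 1, EN = 2, CR = 3. Three views
are provided:

* **Goodman–Kruskal gamma**: rank association over all species pairs,
  (C − D)/(C + D) with concordant pairs C, discordant pairs D, and tied
  pairs excluded. An asymptotic z-test is available as an optional extra.
* **Binary skill**: sensitivity, specificity and the true skill statistic
  (TSS = sensitivity + specificity − 1) for the threatened (VU/EN/CR)
  versus non-threatened dichotomy.
* **Grouped ordinal differences**: per-group mean of published − predicted
  (positive ⇒ prediction more optimistic) with an empirical central 90%
  interval.

Published data-deficient (DD) species carry no ordinal information and
must be separated out with :func:`split_dd` before computing agreement;
their predictions form their own report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ORDINAL = {"LC": 0, "NT": 0, "LC/NT": 0, "VU": 1, "EN": 2, "CR": 3}
THREATENED = frozenset({"VU", "EN", "CR"})


def to_ordinal(labels: Sequence[str]) -> np.ndarray:
    out = []
    for lab in labels:
        if lab not in ORDINAL:
            raise ValueError(f"cannot rank category {lab!r} (DD must be split out first)")
        out.append(ORDINAL[lab])
    return np.asarray(out, dtype=np.int64)


def split_dd(df: pd.DataFrame, published_col: str = "published") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a category table into (rankable, data-deficient) parts."""
    dd = df[df[published_col] == "DD"]
    return df[df[published_col] != "DD"], dd


@dataclass
class GammaResult:
    gamma: float
    concordant: int
    discordant: int
    n: int
    z: Optional[float] = None
    p_value: Optional[float] = None
    undefined: bool = False


def gk_gamma(
    published: Sequence[str],
    predicted: Sequence[str],
    significance: bool = False,
) -> GammaResult:
    """Goodman–Kruskal gamma between two ordinal category vectors.

    Computed from the contingency table: C = Σ n_ij · N⁺(i,j) where
    N⁺(i,j) sums cells strictly below-right, and symmetrically for D.
    When every pair is tied (C + D = 0) gamma is undefined and flagged.
    """
    x = to_ordinal(published)
    y = to_ordinal(predicted)
    if x.size != y.size:
        raise ValueError("label vectors differ in length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    k = 4
    table = np.zeros((k, k), dtype=np.int64)
    np.add.at(table, (x, y), 1)

    concordant = 0
    discordant = 0
    for i in range(k):
        for j in range(k):
            nij = table[i, j]
            if nij == 0:
                continue
            concordant += nij * table[i + 1 :, j + 1 :].sum()
            discordant += nij * table[i + 1 :, :j].sum()
    concordant = int(concordant)
    discordant = int(discordant)

    if concordant + discordant == 0:
        return GammaResult(
            gamma=math.nan, concordant=0, discordant=0, n=x.size, undefined=True
        )
    gamma = (concordant - discordant) / (concordant + discordant)
    res = GammaResult(gamma=gamma, concordant=concordant, discordant=discordant, n=x.size)
    if significance and abs(gamma) < 1:
        # asymptotic z for H0: gamma = 0 (Goodman & Kruskal approximation)
        z = gamma * math.sqrt((concordant + discordant) / (x.size * (1 - gamma**2)))
        from scipy.stats import norm

        res.z = z
        res.p_value = 2 * norm.sf(abs(z))
    return res


@dataclass
class SkillResult:
    sensitivity: Optional[float]
    specificity: Optional[float]
    tss: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


def binary_skill(
    published: Sequence[str],
    predicted: Sequence[str],
    threatened: frozenset = THREATENED,
) -> SkillResult:
    """Sensitivity/specificity/TSS on the threatened dichotomy.

    Sensitivity is the fraction of published-threatened species predicted
    threatened; specificity the fraction of published-non-threatened
    predicted non-threatened. A statistic whose reference class is absent
    is returned as None rather than a silent 0/0.
    """
    pub_t = np.asarray([lab in threatened for lab in published])
    pred_t = np.asarray([lab in threatened for lab in predicted])
    if pub_t.size != pred_t.size:
        raise ValueError("label vectors differ in length")
    tp = int((pub_t & pred_t).sum())
    fn = int((pub_t & ~pred_t).sum())
    tn = int((~pub_t & ~pred_t).sum())
    fp = int((~pub_t & pred_t).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    tss = sens + spec - 1 if (sens is not None and spec is not None) else None
    return SkillResult(sensitivity=sens, specificity=spec, tss=tss, tp=tp, fp=fp, tn=tn, fn=fn)


def grouped_difference(
    published: Sequence[str],
    predicted: Sequence[str],
    groups: Sequence[str],
    interval: float = 0.90,
) -> pd.DataFrame:
    """Per-group mean ordinal difference (published − predicted) with a
    central empirical interval (default 90%, linear interpolation)."""
    diff = to_ordinal(published) - to_ordinal(predicted)
    df = pd.DataFrame({"group": list(groups), "diff": diff})
    lo_q = (1 - interval) / 2 * 100
    hi_q = 100 - lo_q
    rows = []
    for name, sub in df.groupby("group", sort=True):
        d = sub["diff"].to_numpy()
        rows.append(
            {
                "group": name,
                "n": d.size,
                "mean_diff": float(d.mean()),
                "lo": float(np.percentile(d, lo_q)),
                "hi": float(np.percentile(d, hi_q)),
            }
        )
    return pd.DataFrame(rows)


def agreement_report(published: Sequence[str], predicted: Sequence[str]) -> dict:
    """JSON-ready summary of all agreement statistics."""
    g = gk_gamma(published, predicted)
    s = binary_skill(published, predicted)
    diff = to_ordinal(published) - to_ordinal(predicted)
    return {
        "n": int(len(published)),
        "gk_gamma": None if g.undefined else g.gamma,
        "sensitivity": s.sensitivity,
        "specificity": s.specificity,
        "tss": s.tss,
        "mean_ordinal_difference": float(diff.mean()),
        "confusion": {"tp": s.tp, "fp": s.fp, "tn": s.tn, "fn": s.fn},
    }
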