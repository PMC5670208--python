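"""Correlation stage: receptor availability versus drug-effect measures.

Relates per-subject right-amygdala VT to the drug-induced anxiety change
(1-2 h window mean, drug minus placebo) and to the drug effect on the
amygdala SSQ ratio; post-hoc specificity checks correlate VT with the
psychotic-symptom change and the SSQ effect with the fearful-face SCR
count change.  Associations use Pearson's product-moment correlation with
the t-distributed significance test; no correction is applied across the
primary hypotheses, and every result is reported with its n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "extract_cluster_mean",
    "pearson_corr",
    "AssociationModel",
    "AssociationResults",
    "run_association",
    "DEFAULT_HYPOTHESES",
]

P_FLOOR = 1e-15

# (x column, y column, tier)
DEFAULT_HYPOTHESES = (
    ("vt_right_amygdala", "anxiety_delta", "primary"),
    ("vt_right_amygdala", "ssq_effect", "primary"),
    ("vt_right_amygdala", "psychosis_delta", "post-hoc"),
    ("ssq_effect", "scr_fear_count_delta", "post-hoc"),
)


def extract_cluster_mean(ssq_map, cluster_mask) -> float:
    """Mean of a statistic map over a (boolean or labelled) cluster mask."""
    m = np.asarray(ssq_map, dtype=float)
    mask = np.asarray(cluster_mask).astype(bool)
    if m.shape != mask.shape:
        raise ValueError("map and mask grids differ")
    if not mask.any():
        raise ValueError("empty cluster mask")
    return float(m[mask].mean())


def pearson_corr(x, y, sidedness: str = "two"):
    """Pearson r with its t-test p-value (n - 2 degrees of freedom).

    One-sided tests are directional in the sign of r (p_one = p_two / 2
    for the observed direction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
    p_two = 2.0 * float(stats.t.sf(abs(t), n - 2))
    p = p_two if sidedness == "two" else p_two / 2.0
    return r, max(p, 0.0)


class AssociationResults:
    """Correlation table with primary/post-hoc flags and floor warnings."""

    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        lines = ["VT-effect association report", "=" * 60,
                 f"{'x':<22}{'y':<22}{'n':>3} {'r':>7} {'p(two)':>9} "
                 f"{'p(one)':>9}  tier"]
        for _, row in self.table.iterrows():
            flag = " *floor*" if row["at_floor"] else ""
            lines.append(f"{row['x']:<22}{row['y']:<22}{row['n']:>3d} "
                         f"{row['r']:>7.3f} {row['p_two']:>9.4g} "
                         f"{row['p_one']:>9.4g}  {row['tier']}{flag}")
        return "\n".join(lines)


class AssociationModel:
    """Pearson-correlation analysis over a table of subject records.

    Parameters
    ----------
    records : DataFrame
        One row per subject; must contain every column referenced by the
        hypotheses (default: VT vs anxiety change and VT vs SSQ effect as
        primary, the specificity checks as post-hoc).
    hypotheses : iterable of (x, y, tier)
    """

    def __init__(self, records: pd.DataFrame,
                 hypotheses=DEFAULT_HYPOTHESES):
        if len(records) < 3:
            raise ValueError("need at least 3 complete records")
        self.records = records.reset_index(drop=True)
        self.hypotheses = tuple(hypotheses)
        missing = {c for x, y, _ in self.hypotheses for c in (x, y)} \
            - set(records.columns)
        if missing:
            raise ValueError(f"records lack columns {sorted(missing)}")

    @classmethod
    def from_components(cls, vt, anxiety_delta, ssq_effect,
                        psychosis_delta=None, scr_fear_count_delta=None,
                        subjects=None, hypotheses=None):
        """Assemble the records table from per-measure vectors."""
        n = len(vt)
        data = {"subject": subjects if subjects is not None
                else [f"S{i + 1:02d}" for i in range(n)],
                "vt_right_amygdala": vt, "anxiety_delta": anxiety_delta,
                "ssq_effect": ssq_effect}
        hyps = list(DEFAULT_HYPOTHESES[:2])
        if psychosis_delta is not None:
            data["psychosis_delta"] = psychosis_delta
            hyps.append(DEFAULT_HYPOTHESES[2])
        if scr_fear_count_delta is not None:
            data["scr_fear_count_delta"] = scr_fear_count_delta
            hyps.append(DEFAULT_HYPOTHESES[3])
        return cls(pd.DataFrame(data), hypotheses or tuple(hyps))

    def fit(self) -> AssociationResults:
        rows = []
        for x, y, tier in self.hypotheses:
            sub = self.records[[x, y]].dropna()
            r, p_two = pearson_corr(sub[x], sub[y], "two")
            p_one = p_two / 2.0 if r >= 0 else 1.0 - p_two / 2.0
            rows.append({"x": x, "y": y, "n": len(sub), "r": r,
                         "p_two": max(p_two, P_FLOOR),
                         "p_one": max(p_one, P_FLOOR),
                         "tier": tier,
                         "at_floor": p_two <= P_FLOOR})
        return AssociationResults(self, pd.DataFrame(rows))


def run_association(records: pd.DataFrame,
                    hypotheses=DEFAULT_HYPOTHESES) -> pd.DataFrame:
    """Functional wrapper: fit the association model, return the table."""
    return AssociationModel(records, hypotheses).fit().table
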