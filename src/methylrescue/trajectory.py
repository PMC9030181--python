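"""Genome-wide aging-trajectory regression.

For each bin the old - young methylation difference is the aging baseline
x; the treated-group difference (treated - old, or treated - young) is the
response y.  If the treated methylome is a convex mixture
``treated = lambda * old + (1 - lambda) * young`` then

    y = treated - old   = (lambda - 1) * x    => lambda = 1 + slope
    y = treated - young = lambda * x          => lambda = slope

so the OLS slope of y on x estimates the mixing coefficient: how much of
the normal aging change the treated group retains.  Bins in the second and
fourth quadrants (treated moved against the aging direction) dominate when
lambda < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ValidationError

__all__ = ["TrajectoryFit", "fit_trajectory", "quadrant_summary"]

RESPONSES = ("treated-old", "treated-young")


@dataclass
class TrajectoryFit:
    """OLS fit of treated-group methylation differences on the aging baseline."""

    x_def: str
    y_def: str
    response: str
    slope: float
    intercept: float
    pcc: float
    lambda_hat: float
    n_bins: int
    quadrant_counts: dict[str, int]
    scatter: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        q = self.quadrant_counts
        lines = [
            f"trajectory fit: {self.y_def} ~ {self.x_def} over {self.n_bins} bins",
            f"  slope      {self.slope:+.4f}",
            f"  intercept  {self.intercept:+.4f}",
            f"  PCC        {self.pcc:+.4f}",
            f"  lambda_hat {self.lambda_hat:.4f}  (treated ~ {self.lambda_hat:.3f}*old + {1 - self.lambda_hat:.3f}*young)",
            f"  quadrants  Q1={q['Q1']} Q2={q['Q2']} Q3={q['Q3']} Q4={q['Q4']}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        row = {
            "x_def": self.x_def,
            "y_def": self.y_def,
            "slope": self.slope,
            "intercept": self.intercept,
            "pcc": self.pcc,
            "lambda_hat": self.lambda_hat,
            "n_bins": self.n_bins,
            **{k.lower(): v for k, v in self.quadrant_counts.items()},
        }
        return pd.DataFrame([row])


def fit_trajectory(
    group_levels: pd.DataFrame,
    young: str = "young",
    old: str = "old",
    treated: str = "DR",
    response: str = "treated-old",
) -> TrajectoryFit:
    """Regress per-bin treated differences on the old - young baseline.

    ``group_levels`` is a bin x group DataFrame of methylation levels.  The
    regression is ordinary least squares with an unconstrained intercept;
    the Pearson correlation is computed on the same (x, y) pairs.  Quadrant
    counts classify bins by the signs of x and y, excluding bins on either
    axis.
    """
    if response not in RESPONSES:
        raise ValidationError(f"response must be one of {RESPONSES}, got {response!r}")
    for g in (young, old, treated):
        if g not in group_levels.columns:
            raise ValidationError(f"group {g!r} missing from group levels")
    x = (group_levels[old] - group_levels[young]).to_numpy(float)
    if response == "treated-old":
        y = (group_levels[treated] - group_levels[old]).to_numpy(float)
        y_def = f"{treated} - {old}"
    else:
        y = (group_levels[treated] - group_levels[young]).to_numpy(float)
        y_def = f"{treated} - {young}"
    if x.size < 3:
        raise ValidationError("need at least 3 bins to fit a trajectory")
    var_x = np.var(x)
    if var_x == 0:
        raise ValidationError("degenerate baseline: old - young differences have zero variance")

    slope = float(np.cov(x, y, bias=True)[0, 1] / var_x)
    intercept = float(np.mean(y) - slope * np.mean(x))
    sd_y = float(np.std(y))
    pcc = slope * float(np.std(x)) / sd_y if sd_y > 0 else 0.0
    lambda_hat = 1.0 + slope if response == "treated-old" else slope

    quadrants = {
        "Q1": int(np.sum((x > 0) & (y > 0))),
        "Q2": int(np.sum((x < 0) & (y > 0))),
        "Q3": int(np.sum((x < 0) & (y < 0))),
        "Q4": int(np.sum((x > 0) & (y < 0))),
    }
    scatter = pd.DataFrame({"region": group_levels.index, "x": x, "y": y}).reset_index(drop=True)
    return TrajectoryFit(
        x_def=f"{old} - {young}",
        y_def=y_def,
        response=response,
        slope=slope,
        intercept=intercept,
        pcc=pcc,
        lambda_hat=lambda_hat,
        n_bins=int(x.size),
        quadrant_counts=quadrants,
        scatter=scatter,
    )


def quadrant_summary(fit: TrajectoryFit) -> dict:
    """Interpret the quadrant counts of a treated - old fit.

    Q2 bins were hypomethylated in normal aging but held higher by the
    treatment; Q4 bins were hypermethylated but held lower.  Treatment
    opposing the aging change genome-wide shows as Q2 + Q4 > Q1 + Q3.
    """
    if fit.response != "treated-old":
        raise ValidationError("quadrant interpretation is defined on the treated-old response")
    q = fit.quadrant_counts
    opposing = q["Q2"] + q["Q4"]
    following = q["Q1"] + q["Q3"]
    return {
        "hypo_retained_Q2": q["Q2"],
        "hyper_retained_Q4": q["Q4"],
        "opposing": opposing,
        "following": following,
        "treatment_opposes_aging": opposing > following,
    }
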