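"""Rescue classification of aging calls.

An aging-related feature (a significant young-vs-old DMR or DEG with a
direction) is *ameliorated* by a treatment when the treated group's mean
moved back toward the young value:

* hyper DMR / ODEG (value rose with aging): ameliorated iff the treated
  mean is strictly lower than the old mean;
* hypo DMR / UDEG (value fell with aging): ameliorated iff the treated
  mean is strictly higher than the old mean.

Ties never ameliorate.  No significance is required of the treated-vs-old
contrast by default — the decision is purely directional — but an optional
moderated-test filter can be layered on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .difftest import ShrinkagePrior, moderated_two_sample_test
from .io_formats import SampleSheet, ValidationError

__all__ = [
    "classify_dmr_amelioration",
    "classify_deg_amelioration",
    "amelioration_summary",
    "overlap_sets",
]

_UP = ("hyper", "ODEG")
_DOWN = ("hypo", "UDEG")


def _classify(
    aging_calls: pd.DataFrame,
    group_values: pd.DataFrame,
    treated_group: str,
    old_group: str,
) -> pd.DataFrame:
    sig = aging_calls.loc[aging_calls["significant"]]
    for g in (old_group, treated_group):
        if g not in group_values.columns:
            raise ValidationError(f"group {g!r} missing from group values")
    missing = [f for f in sig["feature_id"] if f not in group_values.index]
    if missing:
        raise ValidationError(
            f"treated group values missing for feature(s): {', '.join(map(str, missing[:5]))}"
        )
    old_value = group_values.loc[sig["feature_id"], old_group].to_numpy(float)
    treated_value = group_values.loc[sig["feature_id"], treated_group].to_numpy(float)
    direction = sig["direction"].to_numpy()
    up = np.isin(direction, _UP)
    down = np.isin(direction, _DOWN)
    ameliorated = (up & (treated_value < old_value)) | (down & (treated_value > old_value))
    return pd.DataFrame(
        {
            "feature_id": sig["feature_id"].to_numpy(),
            "aging_direction": direction,
            "treated_group": treated_group,
            "old_value": old_value,
            "treated_value": treated_value,
            "ameliorated": ameliorated,
        }
    )


def classify_dmr_amelioration(
    aging_dmrs: pd.DataFrame,
    group_levels: pd.DataFrame,
    treated_group: str,
    old_group: str = "old",
    require_significance: bool = False,
    sample_levels: pd.DataFrame | None = None,
    sample_sheet: SampleSheet | None = None,
    prior: ShrinkagePrior | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per aging-DMR rescue decision for one treated group.

    ``aging_dmrs`` is a call table from :func:`methylrescue.difftest.call_dmrs`
    on the young-vs-old contrast; only its significant rows are classified.
    ``group_levels`` is the bin x group mean-methylation matrix.  With
    ``require_significance`` the directional rule is additionally gated on a
    moderated treated-vs-old test at ``p_threshold`` (needs per-sample
    levels and the sample sheet).
    """
    calls = _classify(aging_dmrs, group_levels, treated_group, old_group)
    if require_significance:
        if sample_levels is None or sample_sheet is None:
            raise ValidationError("require_significance needs sample_levels and sample_sheet")
        a = sample_levels.loc[calls["feature_id"], sample_sheet.samples_in(old_group)].to_numpy(float)
        b = sample_levels.loc[calls["feature_id"], sample_sheet.samples_in(treated_group)].to_numpy(float)
        if prior is None:
            from .difftest import _pooled, estimate_prior

            _, _, s_sq, d = _pooled(a, b)
            prior = estimate_prior(s_sq, d)
        _, p = moderated_two_sample_test(a, b, prior)
        calls["ameliorated"] &= np.atleast_1d(p) < p_threshold
    return calls


def classify_deg_amelioration(
    aging_degs: pd.DataFrame,
    group_expression_means: pd.DataFrame,
    treated_group: str,
    old_group: str = "old",
) -> pd.DataFrame:
    """Per aging-DEG rescue decision (directional rule on group mean FPKM)."""
    return _classify(aging_degs, group_expression_means, treated_group, old_group)


def amelioration_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of ameliorated features per aging direction and overall."""
    rows = []
    for direction, sub in calls.groupby("aging_direction"):
        n = len(sub)
        k = int(sub["ameliorated"].sum())
        rows.append({"aging_direction": direction, "n_aging": n, "n_ameliorated": k, "fraction": k / n if n else float("nan")})
    n = len(calls)
    k = int(calls["ameliorated"].sum())
    rows.append({"aging_direction": "all", "n_aging": n, "n_ameliorated": k, "fraction": k / n if n else float("nan")})
    return pd.DataFrame(rows)


def overlap_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Overlap of two treatments' ameliorated feature sets.

    Returns intersection/union counts and the union-fraction overlap,
    overall and per aging direction, plus the sorted id lists.
    """
    def _sets(calls: pd.DataFrame) -> dict[str, set]:
        amel = calls.loc[calls["ameliorated"]]
        by_dir = {d: set(sub["feature_id"]) for d, sub in amel.groupby("aging_direction")}
        by_dir["all"] = set(amel["feature_id"])
        return by_dir

    sets_a, sets_b = _sets(calls_a), _sets(calls_b)
    out: dict = {"per_direction": {}}
    for key in sorted(set(sets_a) | set(sets_b)):
        a = sets_a.get(key, set())
        b = sets_b.get(key, set())
        inter, union = a & b, a | b
        entry = {
            "n_a": len(a),
            "n_b": len(b),
            "intersection": len(inter),
            "union": len(union),
            "fraction": len(inter) / len(union) if union else float("nan"),
            "features": sorted(inter),
        }
        if key == "all":
            out.update(entry)
        else:
            out["per_direction"][key] = entry
    return out
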