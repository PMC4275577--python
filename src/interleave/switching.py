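"""Condition-switch classification of transcription changes.

Given normalized nascent-transcription levels in two conditions (glucose
and galactose in the motivating study), each feature is classed by its
fold change: more than ``threshold``-fold up (``UP3``), more than
``threshold``-fold down (``DOWN3``), or ``UNCHANGED``.  The default
threshold of 3 follows the field's convention of calling only strong
(>threefold) switches after a carbon-source shift.

A second fold-change source (e.g. steady-state poly(A)+ RNA) can be
compared against the nascent one to ask whether a change in transcript
level reflects altered transcription or altered transcript stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import FeatureTable

SWITCH_CLASSES = ("UP3", "DOWN3", "UNCHANGED")
CONCORDANCE_CLASSES = ("TRANSCRIPTION_DRIVEN", "STABILITY_DRIVEN",
                       "INDETERMINATE")


def fold_change(expr_a: float, expr_b: float,
                pseudocount: float = 0.5) -> float:
    """Ratio (b + pseudocount) / (a + pseudocount).

    The pseudocount keeps the ratio defined for features with zero signal
    and makes ``fold_change(a, b) * fold_change(b, a) == 1``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if expr_a < 0 or expr_b < 0:
        raise ValueError("expression levels must be non-negative")
    return (expr_b + pseudocount) / (expr_a + pseudocount)


def classify_switch(table: FeatureTable, cond_a: str, cond_b: str,
                    threshold: float = 3.0,
                    pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-feature fold change cond_b/cond_a and switch class.

    Returns a DataFrame with columns ``feature_id, fc, switch``.  The
    boundary is strict: a feature at exactly ``threshold``-fold is
    UNCHANGED.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = table.expr(cond_a)
    b = table.expr(cond_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression levels must be non-negative")
    fc = (b + pseudocount) / (a + pseudocount)
    switch = np.where(fc > threshold, "UP3",
                      np.where(fc < 1.0 / threshold, "DOWN3", "UNCHANGED"))
    return pd.DataFrame({
        "feature_id": table.df["feature_id"].to_numpy(),
        "fc": fc,
        "switch": switch,
    })


def concordance(fc_primary: float, fc_secondary: float,
                threshold: float = 3.0) -> str:
    """Compare a nascent (primary) and steady-state (secondary) fold change.

    TRANSCRIPTION_DRIVEN when both exceed the threshold in the same
    direction; STABILITY_DRIVEN when only the steady-state change exceeds
    it, or the two disagree in direction beyond it; INDETERMINATE
    otherwise.
    """
    if fc_primary <= 0 or fc_secondary <= 0:
        raise ValueError("fold changes must be positive")
    lo = 1.0 / threshold
    p_up, p_down = fc_primary > threshold, fc_primary < lo
    s_up, s_down = fc_secondary > threshold, fc_secondary < lo
    if (p_up and s_up) or (p_down and s_down):
        return "TRANSCRIPTION_DRIVEN"
    if (s_up or s_down) and not (p_up or p_down):
        return "STABILITY_DRIVEN"
    if (p_up and s_down) or (p_down and s_up):
        return "STABILITY_DRIVEN"
    return "INDETERMINATE"


def classify_concordance(switches: pd.DataFrame,
                         fc_secondary: pd.Series | dict,
                         threshold: float = 3.0) -> pd.DataFrame:
    """Vector version of :func:`concordance` over a switch table.

    ``fc_secondary`` maps feature_id to the steady-state fold change.
    """
    sec = pd.Series(fc_secondary)
    out = switches.copy()
    out["fc_secondary"] = out["feature_id"].map(sec)
    if out["fc_secondary"].isna().any():
        missing = out.loc[out["fc_secondary"].isna(), "feature_id"].tolist()
        raise KeyError(f"no secondary fold change for features {missing[:5]}")
    out["concordance"] = [
        concordance(p, s, threshold)
        for p, s in zip(out["fc"], out["fc_secondary"])
    ]
    return out


def set_overlap(set_a, set_b, universe, name_a: str = "A",
                name_b: str = "B") -> dict:
    """Overlap of two gene sets with a hypergeometric upper-tail p-value.

    ``p_hyper`` is the probability of drawing at least the observed
    overlap when |set_a| genes are sampled without replacement from a
    universe containing |set_b| successes.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe:
        raise ValueError("set_a is not a subset of the universe")
    if not set_b <= universe:
        raise ValueError("set_b is not a subset of the universe")
    n_a, n_b, n_u = len(set_a), len(set_b), len(universe)
    k = len(set_a & set_b)
    p = float(hypergeom.sf(k - 1, n_u, n_b, n_a)) if n_a else 1.0
    return {
        "set_a_name": name_a,
        "set_b_name": name_b,
        "n_a": n_a,
        "n_b": n_b,
        "n_universe": n_u,
        "n_overlap": k,
        "fraction_of_a": k / n_a if n_a else float("nan"),
        "p_hyper": min(p, 1.0),
    }


def switch_counts(switches: pd.DataFrame) -> dict[str, int]:
    """Counts per switch class; classes absent from the table count 0."""
    counts = switches["switch"].value_counts().to_dict()
    return {cls: int(counts.get(cls, 0)) for cls in SWITCH_CLASSES}
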