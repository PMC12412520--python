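"""Normalized metabolic activity and discrete viability classes.

The resazurin-type readout of each droplet is normalized between the basal
signal of the reagent alone (no cells) and the mean fluorescence of the
no-drug control droplets of the same experiment:

    activity(%) = (I - B) / (mean_i(I0_i) - B) * 100

Values outside [0, 100] are kept as-is (biological spread around the control
level is real signal, not error).  Classes: two-class scheme splits at 50%
("low" strictly below), three-class scheme at 25% and 75% ("low" strictly
below 25, "high" strictly above 75, "intermediate" between).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateAssayError

__all__ = [
    "normalize_metabolic_activity",
    "discretize_viability",
    "label_readouts",
]


def normalize_metabolic_activity(intensity, basal: float, controls) -> float | np.ndarray:
    """Percent metabolic activity of droplet fluorescence ``intensity``.

    ``controls`` are the raw fluorescence values of the no-drug droplets of
    the same experiment; ``basal`` is the reagent-only signal.  Raises
    :class:`DegenerateAssayError` when the control mean does not exceed the
    basal signal.
    """
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("controls must be non-empty")
    denom = controls.mean() - basal
    if denom <= 0:
        raise DegenerateAssayError(
            f"control mean {controls.mean():.3g} does not exceed basal {basal:.3g}"
        )
    out = (np.asarray(intensity, dtype=float) - basal) / denom * 100.0
    return float(out) if out.ndim == 0 else out


def discretize_viability(percent, scheme: str = "two_class"):
    """Viability class label(s) for metabolic activity percentage(s).

    two_class: "low" strictly below 50%, else "high".
    three_class: "low" strictly below 25%, "high" strictly above 75%,
    "intermediate" otherwise.  Boundary values go to the non-strict side.
    """
    p = np.asarray(percent, dtype=float)
    if scheme == "two_class":
        out = np.where(p < 50.0, "low", "high")
    elif scheme == "three_class":
        out = np.where(p < 25.0, "low", np.where(p > 75.0, "high", "intermediate"))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return str(out[()]) if p.ndim == 0 else out


def label_readouts(readouts: pd.DataFrame, scheme: str = "two_class") -> pd.DataFrame:
    """Per-droplet metabolic activity and viability classes from a raw table.

    Expects columns ``droplet_id, experiment_id, raw_fluorescence,
    is_control, is_basal``.  The basal signal and the control mean are
    estimated per experiment (batch gains make pooling across experiments
    incorrect).  Basal-only rows are consumed for the estimate and not
    returned.
    """
    required = {"droplet_id", "experiment_id", "raw_fluorescence", "is_control", "is_basal"}
    missing = required - set(readouts.columns)
    if missing:
        raise ValueError(f"readout table lacks columns: {sorted(missing)}")
    out_rows = []
    for exp_id, grp in readouts.groupby("experiment_id", sort=False):
        basal_rows = grp[grp["is_basal"]]
        if basal_rows.empty:
            raise ValueError(f"experiment {exp_id} has no basal droplets")
        basal = float(basal_rows["raw_fluorescence"].mean())
        controls = grp[grp["is_control"] & ~grp["is_basal"]]["raw_fluorescence"]
        if controls.empty:
            raise ValueError(f"experiment {exp_id} has no control droplets")
        droplets = grp[~grp["is_basal"]]
        activity = normalize_metabolic_activity(
            droplets["raw_fluorescence"].to_numpy(), basal, controls.to_numpy()
        )
        for (_, row), act in zip(droplets.iterrows(), activity):
            out_rows.append(
                {
                    "spheroid_id": row["droplet_id"],
                    "experiment_id": exp_id,
                    "metabolic_activity_pct": float(act),
                    "class2": discretize_viability(act, "two_class"),
                    "class3": discretize_viability(act, "three_class"),
                }
            )
    out = pd.DataFrame(out_rows)
    if scheme not in ("two_class", "three_class"):
        raise ValueError(f"unknown scheme {scheme!r}")
    return out
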