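"""Binary-mask overlap metrics for segmentation evaluation.

For a predicted mask P and a truth mask T over the same pixel grid:

* Dice        = 2|P∩T| / (|P| + |T|)
* IoU         = |P∩T| / |P∪T|
* sensitivity = |P∩T| / |T|          (true-positive rate)
* specificity = |¬P∩¬T| / |¬T|       (true-negative rate)

Degenerate-denominator conventions (fixed here because no single standard
exists): if both masks are empty, dice = iou = sensitivity = 1 (perfect
agreement on "nothing to segment"); if only the truth is empty,
sensitivity = 1 and dice = iou = 0 for a non-empty prediction; if every
pixel is truth-foreground, specificity = 1.  All outputs lie in [0, 1],
and dice = 2·iou/(1+iou) algebraically.
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractError

METRIC_NAMES = ("dice", "iou", "sensitivity", "specificity")


def overlap_metrics(prediction: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Compute (dice, iou, sensitivity, specificity) for two binary masks.

    Raises :class:`ContractError` on shape mismatch or non-binary input.
    """
    prediction = np.asarray(prediction)
    truth = np.asarray(truth)
    if prediction.shape != truth.shape:
        raise ContractError(
            f"mask shape mismatch: prediction {prediction.shape} vs truth {truth.shape}"
        )
    for name, arr in (("prediction", prediction), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ContractError(f"{name} mask is not binary")

    p = prediction.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    p_size = int(np.count_nonzero(p))
    t_size = int(np.count_nonzero(t))
    union = p_size + t_size - tp
    tn = int(np.count_nonzero(~p & ~t))
    negatives = p.size - t_size

    dice = 1.0 if p_size + t_size == 0 else 2.0 * tp / (p_size + t_size)
    iou = 1.0 if union == 0 else tp / union
    sensitivity = 1.0 if t_size == 0 else tp / t_size
    specificity = 1.0 if negatives == 0 else tn / negatives
    return {
        "dice": dice,
        "iou": iou,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }
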