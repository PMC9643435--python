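"""Model interpretation: relevance maps, coefficient readout and
prototype (top true positive) extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lymphodyn.classifiers import Level1Model
from lymphodyn.nn import Sequential, lrp_explain as _nn_lrp


@dataclass
class Prototype:
    sample_index: int
    score: float
    phenotype: str = ""
    kind: str = "patch"  # "patch" or "track"


def lrp_explain(model, x: np.ndarray, target_class: int, eps: float = 1e-6) -> np.ndarray:
    """Relevance map with the same shape as the model input.

    Convolutional models use the layer-wise backward pass (ε-rule on
    dense layers, z⁺ on convolutions); the linear level-1 model has the
    closed form relevance_i = w_i · x_i on standardized features.
    """
    if isinstance(model, Level1Model):
        if not model.fitted:
            raise ValueError("model is not fitted")
        z = model.scaler.transform(np.atleast_2d(x))
        w = model.coef_ if target_class == 1 else -model.coef_
        return z * w
    if isinstance(model, Sequential):
        return _nn_lrp(model, np.atleast_2d(x) if x.ndim == 1 else x, target_class, eps=eps)
    raise ValueError(f"unsupported model type: {type(model).__name__}")


def top_true_positives(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int,
    phenotype: str = "",
    kind: str = "patch",
    threshold: float = 0.5,
) -> list[Prototype]:
    """The k correctly classified positives with the highest scores.

    Ties resolve by ascending sample index.  Fewer than k true positives
    returns all of them (with a warning when there are none).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    tp = np.flatnonzero((labels == 1) & (scores >= threshold))
    if tp.size == 0:
        warnings.warn("no true positives to extract prototypes from")
        return []
    order = tp[np.lexsort((tp, -scores[tp]))]
    return [
        Prototype(sample_index=int(i), score=float(scores[i]), phenotype=phenotype, kind=kind)
        for i in order[:k]
    ]


def coefficient_report(model: Level1Model, feature_names=None) -> pd.DataFrame:
    """Features ranked by |coefficient| of the fitted level-1 model.

    Near-duplicate feature columns in the training data trigger a
    collinearity warning, since coefficient magnitudes are then not
    individually meaningful.
    """
    if not getattr(model, "fitted", False):
        raise ValueError("model is not fitted")
    if feature_names is None:
        feature_names = model.feature_names
    coefs = model.coef_
    if len(feature_names) != len(coefs):
        raise ValueError("feature_names length does not match coefficients")
    corr = getattr(model, "_train_corr", None)
    if corr is not None:
        off = np.abs(corr - np.eye(len(coefs)))
        if np.nanmax(off) > 0.999:
            i, j = np.unravel_index(np.nanargmax(off), off.shape)
            warnings.warn(
                f"collinear features detected: {feature_names[i]} ~ {feature_names[j]}"
            )
    df = pd.DataFrame({"feature": list(feature_names), "coefficient": coefs})
    df["abs_coefficient"] = df["coefficient"].abs()
    return df.sort_values(
        ["abs_coefficient", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


def positive_relevance_fraction(relevance: np.ndarray, mask: np.ndarray) -> float:
    """Share of positive relevance landing inside a boolean mask."""
    pos = np.clip(relevance, 0, None)
    total = pos.sum()
    if total == 0:
        return 0.0
    return float(pos[mask].sum() / total)
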