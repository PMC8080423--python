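"""Ordinal label representations and the mappings between them.

An ordinal problem has classes 1..K carrying a natural order (e.g. grades of
cervical dysplasia from normal to carcinoma in situ).  Three representations of
a label are used throughout the package:

* the integer class index ``k*`` in ``{1..K}`` (:class:`OrdinalLabel`);
* its one-hot vector of length K (``1(k = k*)``);
* its cumulative (ordinal) code of length K-1, entry m being ``1(m < k*)`` —
  the targets of ordinal-encoding (OE) models whose K-1 sigmoid outputs each
  decide "does the class exceed threshold m?".

Class indices are 1-based in the public API; any 0-based indexing is an
internal detail and never appears in serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalLabel",
    "encode_one_hot",
    "encode_cumulative",
    "decode_cumulative",
    "cumulative_to_probabilities",
    "as_class_probabilities",
    "read_label_manifest",
    "write_label_manifest",
]

#: Tolerance used when validating that probability vectors sum to one.
SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class OrdinalLabel:
    """A true class index ``k_star`` in ``{1..K}`` for a K-class ordinal problem."""

    k_star: int
    K: int

    def __post_init__(self) -> None:
        if int(self.K) != self.K or self.K < 2:
            raise ValueError(f"K must be an integer >= 2, got {self.K!r}")
        if int(self.k_star) != self.k_star or not (1 <= self.k_star <= self.K):
            raise ValueError(
                f"k_star must be an integer in [1, {self.K}], got {self.k_star!r}"
            )

    def __int__(self) -> int:
        return int(self.k_star)


def encode_one_hot(label: OrdinalLabel) -> np.ndarray:
    """Return the length-K one-hot vector ``1(k = k*)`` of *label*."""
    out = np.zeros(label.K, dtype=float)
    out[label.k_star - 1] = 1.0
    return out


def encode_cumulative(label: OrdinalLabel) -> np.ndarray:
    """Return the length-(K-1) cumulative code, entry m (1-based) being ``1(m < k*)``.

    The lowest class maps to all zeros, the highest to all ones.
    """
    m = np.arange(1, label.K)
    return (m < label.k_star).astype(float)


def decode_cumulative(
    outputs: np.ndarray, threshold: float = 0.5, K: int | None = None
) -> OrdinalLabel:
    """Invert a cumulative code (possibly soft, possibly non-monotone) to a class.

    The predicted class is ``1 + #{m : outputs[m] > threshold}`` — the sum rule.
    Counting is robust to non-monotone raw model outputs: ``[0.9, 0.2, 0.8]``
    decodes to class 3 regardless of where the dip occurs.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 1 or outputs.size < 1:
        raise ValueError("outputs must be a 1-D vector of length K-1 >= 1")
    if np.any(outputs < 0) or np.any(outputs > 1):
        raise ValueError("cumulative outputs must lie in [0, 1]")
    if K is None:
        K = outputs.size + 1
    elif K != outputs.size + 1:
        raise ValueError(f"K={K} inconsistent with {outputs.size} outputs")
    k_star = 1 + int(np.sum(outputs > threshold))
    return OrdinalLabel(k_star=k_star, K=K)


def cumulative_to_probabilities(outputs: np.ndarray) -> np.ndarray:
    """Convert K-1 cumulative outputs into a length-K class-probability vector.

    Raw outputs are first projected onto monotone non-increasing form by a
    running minimum, ``c'_m = min(c_1, .., c_m)``, which is idempotent and exact
    on valid codes; successive differences then give the class masses
    ``p_1 = 1 - c'_1``, ``p_k = c'_{k-1} - c'_k``, ``p_K = c'_{K-1}``.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 1 or outputs.size < 1:
        raise ValueError("outputs must be a 1-D vector of length K-1 >= 1")
    if np.any(outputs < 0) or np.any(outputs > 1):
        raise ValueError("cumulative outputs must lie in [0, 1]")
    c = np.minimum.accumulate(outputs)
    probs = np.empty(outputs.size + 1, dtype=float)
    probs[0] = 1.0 - c[0]
    probs[1:-1] = c[:-1] - c[1:]
    probs[-1] = c[-1]
    return probs


def as_class_probabilities(values: np.ndarray, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    """Validate and return *values* as a class-probability vector.

    Raises ``ValueError`` if any entry is negative or the sum deviates from one
    by more than *atol*.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("class probabilities must be a 1-D vector of length K >= 2")
    if np.any(values < 0):
        raise ValueError("class probabilities must be non-negative")
    if abs(values.sum() - 1.0) > atol:
        raise ValueError(f"class probabilities must sum to 1 (got {values.sum()!r})")
    return values


def read_label_manifest(path) -> pd.DataFrame:
    """Read a ``path,label`` CSV manifest; labels are 1-based integer classes."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    labels = df["label"].to_numpy()
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == labels.astype(int)):
            raise ValueError("manifest labels must be integers")
        df["label"] = labels.astype(int)
    if df["label"].min() < 1:
        raise ValueError("manifest labels must be 1-based (minimum label < 1 found)")
    return df


def write_label_manifest(df: pd.DataFrame, path) -> None:
    """Write a ``path,label`` CSV manifest."""
    df.loc[:, ["path", "label"]].to_csv(path, index=False)
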