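"""Estimated-kernel container shared by all estimators."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["KernelEstimate"]


@dataclass(frozen=True)
class KernelEstimate:
    """An estimated attachment kernel on the integer degree grid 0..K.

    ``A_hat[k]`` is the estimate at degree ``k``; degrees at which the
    estimator is undefined carry ``NaN`` (missing), which is distinct from
    an estimated value of 0.  The kernel is only identifiable up to a
    multiplicative constant, so every estimate records the normalization
    convention applied (by default: value 1 at a reference degree).
    """

    degrees: np.ndarray
    A_hat: np.ndarray
    method: str
    normalization: str = "none"
    variances: Optional[np.ndarray] = None
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    bin_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A_hat, dtype=float)
        if A.shape != np.asarray(self.degrees).shape:
            raise ValueError("degrees and A_hat must have the same shape")
        with np.errstate(invalid="ignore"):
            if np.nanmin(A, initial=np.inf) < 0:
                raise ValueError("estimated kernel values must be non-negative")
        object.__setattr__(self, "A_hat", A)
        object.__setattr__(self, "degrees", np.asarray(self.degrees, dtype=np.int64))

    @property
    def K(self) -> int:
        return int(self.degrees.max())

    def supported(self) -> np.ndarray:
        """Mask of degrees with a defined, positive estimate."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.A_hat) & (self.A_hat > 0)

    def reference_degree(self, ref_degree: int = 1) -> int:
        """``ref_degree`` if supported, else the smallest supported degree."""
        sup = self.supported()
        if not sup.any():
            raise ValueError("estimate has no supported degree")
        pos = np.where(self.degrees == ref_degree)[0]
        if pos.size and sup[pos[0]]:
            return ref_degree
        return int(self.degrees[sup][0])

    def normalized(self, ref_degree: int = 1) -> "KernelEstimate":
        """Rescale so the kernel equals 1 at the reference degree.

        Falls back to the smallest supported degree when ``ref_degree`` has
        no defined positive value.  Variances scale with the square of the
        factor; confidence bounds scale linearly.
        """
        ref = self.reference_degree(ref_degree)
        scale = float(self.A_hat[np.where(self.degrees == ref)[0][0]])
        return replace(
            self,
            A_hat=self.A_hat / scale,
            variances=None if self.variances is None else self.variances / scale**2,
            ci_lower=None if self.ci_lower is None else self.ci_lower / scale,
            ci_upper=None if self.ci_upper is None else self.ci_upper / scale,
            normalization=f"A_hat at degree {ref} fixed to 1",
        )

    def to_frame(self):
        import pandas as pd

        cols = {"k": self.degrees, "A_hat": self.A_hat}
        if self.variances is not None:
            cols["variance"] = self.variances
        if self.ci_lower is not None:
            cols["ci_lo"] = self.ci_lower
            cols["ci_hi"] = self.ci_upper
        if self.bin_index is not None:
            cols["bin_index"] = self.bin_index
        return pd.DataFrame(cols)
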