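"""Inter-observer agreement between binary labelings: Cohen's kappa.

For two observers' voxel masks A and B evaluated over a common voxel set,

    po = P(A == B)                          observed agreement
    pe = pA*pB + (1-pA)*(1-pB)              chance agreement from marginals
    kappa = (po - pe) / (1 - pe)

kappa corrects raw agreement for the agreement two independent raters with
the same positive rates would reach by chance — essential here because
vessel labels are sparse (a few percent of the ROI), so raw voxel
agreement is near 1 for any pair of sparse masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementResult", "cohens_kappa"]


@dataclass(frozen=True)
class AgreementResult:
    """Observed agreement, chance agreement and Cohen's kappa."""

    po: float
    pe: float
    kappa: float
    n_voxels: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.po <= 1.0 and 0.0 <= self.pe <= 1.0):
            raise ValueError("agreement fractions must lie in [0, 1]")


def cohens_kappa(mask_a: np.ndarray, mask_b: np.ndarray,
                 roi: np.ndarray | None = None) -> AgreementResult:
    """Voxel-wise Cohen's kappa between two binary masks.

    When an ROI is given, only voxels inside it are evaluated (the usual
    mode: agreement about vessels within the retinal slab).  When both
    raters are constant — pe = 1 — kappa is undefined; the result carries
    ``undefined=True`` with kappa NaN, except in the degenerate-but-
    unanimous case po = 1, reported as kappa = 1.
    """
    a = np.asarray(mask_a) != 0
    b = np.asarray(mask_b) != 0
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi) != 0
        if roi.shape != a.shape:
            raise ValueError(f"ROI shape {roi.shape} does not match {a.shape}")
        if not roi.any():
            raise ValueError("ROI is empty")
        a, b = a[roi], b[roi]
    else:
        a, b = a.ravel(), b.ravel()

    n = a.size
    if n == 0:
        raise ValueError("no voxels to evaluate")
    po = float(np.mean(a == b))
    pa = float(a.mean())
    pb = float(b.mean())
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    if pe >= 1.0:
        # both raters constant: chance-corrected agreement is undefined,
        # but unanimity is conventionally reported as kappa = 1
        kappa = 1.0 if po == 1.0 else float("nan")
        return AgreementResult(po, 1.0, kappa, n, undefined=(po != 1.0))
    return AgreementResult(po, pe, (po - pe) / (1.0 - pe), n)
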