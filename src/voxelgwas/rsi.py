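"""Tissue-fraction features from restriction-spectrum-imaging coefficients.

Restriction spectrum imaging models the diffusion signal in each voxel as a
mixture of spherical-harmonic (SH) bases for three water compartments:
restricted (intracellular), hindered (extracellular), and free water.  From
the fitted coefficients, three unitless volume-fraction features in [0, 1]
are derived:

* ``N0`` -- restricted isotropic fraction: |zeroth-order restricted
  coefficient| / Euclidean norm of all model coefficients (cell bodies);
* ``ND`` -- restricted directional fraction: Euclidean norm of the second-
  and fourth-order restricted coefficients / norm of all coefficients
  (axons, dendrites);
* ``NF`` -- free-water fraction: |zeroth-order free-water coefficient| /
  norm of all coefficients.

The order-2/4 aggregate is taken as the Euclidean norm over those
coefficients rather than their algebraic sum: the norm is invariant under
rotations of the voxel frame (which mix coefficients within an SH order)
and keeps the feature inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ConfigurationError

_ORDER_SIZES = {0: 1, 2: 5, 4: 9}


@dataclass
class SHCoefficientSet:
    """Per-voxel spherical-harmonic model coefficients.

    All arrays share a leading voxel shape (any dimensionality) with the
    coefficient index on the last axis.  Restricted-compartment groups must
    have the real-SH sizes 1 / 5 / 9 for orders 0 / 2 / 4; the hindered
    compartment has at least one coefficient and free water exactly one.
    """

    restricted_order0: np.ndarray
    restricted_order2: np.ndarray
    restricted_order4: np.ndarray
    hindered: np.ndarray
    free_order0: np.ndarray

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("restricted_order0", "restricted_order2",
                     "restricted_order4", "hindered", "free_order0"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim == 0:
                a = a.reshape(1, 1)
            setattr(self, name, a)
            arrs[name] = a
        for name, order in (("restricted_order0", 0), ("restricted_order2", 2),
                            ("restricted_order4", 4)):
            if arrs[name].shape[-1] != _ORDER_SIZES[order]:
                raise ConfigurationError(
                    f"{name} must have {_ORDER_SIZES[order]} coefficients, "
                    f"got {arrs[name].shape[-1]}")
        if arrs["hindered"].shape[-1] < 1:
            raise ConfigurationError("hindered compartment needs >= 1 coefficient")
        if arrs["free_order0"].shape[-1] != 1:
            raise ConfigurationError("free water has exactly 1 coefficient")
        shapes = {a.shape[:-1] for a in arrs.values()}
        if len(shapes) != 1:
            raise ConfigurationError(f"inconsistent voxel shapes: {shapes}")
        if any(not np.all(np.isfinite(a)) for a in arrs.values()):
            raise ConfigurationError("non-finite coefficients")

    @property
    def voxel_shape(self) -> tuple[int, ...]:
        return self.restricted_order0.shape[:-1]

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.restricted_order0, self.restricted_order2,
                               self.restricted_order4, self.hindered,
                               self.free_order0], axis=-1)


@dataclass
class TissueFractionMaps:
    """N0 / ND / NF per voxel with a validity mask (False where all coefficients are 0)."""

    n0: np.ndarray
    nd: np.ndarray
    nf: np.ndarray
    valid: np.ndarray


def compute_tissue_fractions(sh: SHCoefficientSet) -> TissueFractionMaps:
    """Normalize SH coefficient groups into the N0 / ND / NF fractions.

    Voxels whose full coefficient vector is zero are marked invalid and get
    zero fractions; no division by zero ever occurs.
    """
    full = sh.stacked()
    norm = np.linalg.norm(full, axis=-1)
    valid = norm > 0
    safe = np.where(valid, norm, 1.0)

    n0 = np.abs(sh.restricted_order0[..., 0]) / safe
    directional = np.concatenate([sh.restricted_order2, sh.restricted_order4], axis=-1)
    nd = np.linalg.norm(directional, axis=-1) / safe
    nf = np.abs(sh.free_order0[..., 0]) / safe

    zero = ~valid
    for arr in (n0, nd, nf):
        arr[zero] = 0.0
    return TissueFractionMaps(n0=n0, nd=nd, nf=nf, valid=valid)
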