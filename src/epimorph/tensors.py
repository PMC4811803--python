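"""Algebra of symmetric 2x2 tensors and tensor fields.

All deformation-rate, texture and stress quantities handled by this package
are symmetric second-order tensors in the image plane.  The inner product
used throughout carries a 1/d normalization (d = 2), under which the identity
tensor has unit norm; for two trace-free ("deviatoric") tensors drawn as
nematic bars, the product equals ``|Q||Q'| cos(2*dtheta)`` where ``dtheta``
is the angle between the bars.  This makes alignment coefficients and
parallel components directly interpretable as orientation averages.

Angles are measured counterclockwise from the +x image axis and stored in
[0, pi) -- bars are headless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: dimension of the plane; enters only the scalar-product normalization
DIM = 2

#: below this deviator norm a bar direction is considered undefined
ANGLE_TOL = 1e-12


@dataclass(frozen=True)
class SymTensor2:
    """A symmetric 2x2 tensor stored as its three independent components.

    Units are contextual: h^-1 for deformation rates, um^2 for textures,
    arbitrary units for stress.
    """

    xx: float
    xy: float
    yy: float

    @classmethod
    def from_matrix(cls, m) -> "SymTensor2":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2):
            raise ValueError(f"expected a 2x2 matrix, got shape {m.shape}")
        if not np.allclose(m[0, 1], m[1, 0], atol=1e-9 * (1 + abs(m).max())):
            raise ValueError("matrix is not symmetric")
        return cls(float(m[0, 0]), 0.5 * float(m[0, 1] + m[1, 0]), float(m[1, 1]))

    @classmethod
    def zero(cls) -> "SymTensor2":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "SymTensor2":
        return cls(1.0, 0.0, 1.0)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.xx, self.xy], [self.xy, self.yy]])

    # -- ring operations (component-wise linear structure) ----------------
    def __add__(self, other: "SymTensor2") -> "SymTensor2":
        return SymTensor2(self.xx + other.xx, self.xy + other.xy, self.yy + other.yy)

    def __sub__(self, other: "SymTensor2") -> "SymTensor2":
        return SymTensor2(self.xx - other.xx, self.xy - other.xy, self.yy - other.yy)

    def __mul__(self, s: float) -> "SymTensor2":
        return SymTensor2(self.xx * s, self.xy * s, self.yy * s)

    __rmul__ = __mul__

    def __truediv__(self, s: float) -> "SymTensor2":
        return SymTensor2(self.xx / s, self.xy / s, self.yy / s)

    def __neg__(self) -> "SymTensor2":
        return SymTensor2(-self.xx, -self.xy, -self.yy)

    @property
    def trace(self) -> float:
        return self.xx + self.yy


@dataclass(frozen=True)
class BarCircle:
    """Circle-and-bar representation of a symmetric tensor.

    ``dilation_rate`` is the isotropic part (signed), ``ce_amplitude`` the
    norm of the deviator (the contraction-elongation magnitude) and
    ``ce_angle`` the bar orientation in [0, pi).  ``angle_defined`` is False
    when the deviator vanishes and the bar has no direction.
    """

    dilation_rate: float
    ce_amplitude: float
    ce_angle: float
    angle_defined: bool = True


class TensorField:
    """A sparse grid (m, n) of symmetric tensors with per-box weights.

    Boxes absent from the field implicitly carry weight 0.
    """

    def __init__(self, m, n, tensors, weights):
        self.m = np.asarray(m, dtype=int)
        self.n = np.asarray(n, dtype=int)
        t = np.asarray(tensors, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("tensors must be an (N, 3) array of (xx, xy, yy)")
        self.components = t
        self.weights = np.asarray(weights, dtype=float)
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not (len(self.m) == len(self.n) == len(t) == len(self.weights)):
            raise ValueError("field arrays must have equal lengths")

    def __len__(self) -> int:
        return len(self.m)

    def tensor(self, i: int) -> SymTensor2:
        xx, xy, yy = self.components[i]
        return SymTensor2(xx, xy, yy)


# ---------------------------------------------------------------------------
# scalar product, norm and decompositions
# ---------------------------------------------------------------------------

def scalar_product(q: SymTensor2, q2: SymTensor2) -> float:
    """Normalized inner product (1/d) Tr(Q Q2^T).

    With this normalization the identity is unitary and, for deviators,
    the product is |Q||Q2| cos(2*dtheta).
    """
    return (q.xx * q2.xx + 2.0 * q.xy * q2.xy + q.yy * q2.yy) / DIM


def tensor_norm(q: SymTensor2) -> float:
    """Norm induced by :func:`scalar_product`; zero iff Q = 0."""
    return float(np.sqrt(scalar_product(q, q)))


def iso_dev_split(q: SymTensor2) -> tuple[float, SymTensor2]:
    """Split into isotropic scalar (Tr Q / 2) and trace-free deviator."""
    iso = 0.5 * q.trace
    return iso, SymTensor2(q.xx - iso, q.xy, q.yy - iso)


def bar_circle(q: SymTensor2, angle_tol: float = ANGLE_TOL) -> BarCircle:
    """Circle-and-bar summary: dilation, CE amplitude, bar orientation.

    The bar points along the eigenvector of the deviator's positive
    eigenvalue, i.e. the direction of elongation.
    """
    iso, dev = iso_dev_split(q)
    amp = tensor_norm(dev)
    if amp <= angle_tol:
        return BarCircle(iso, 0.0, np.nan, angle_defined=False)
    # deviator = a*(cos 2th, sin 2th; sin 2th, -cos 2th) with a = amp
    angle = 0.5 * np.arctan2(dev.xy, dev.xx)
    if angle < 0.0:
        angle += np.pi
    return BarCircle(iso, amp, float(angle % np.pi), angle_defined=True)


def from_bar_circle(bc: BarCircle) -> SymTensor2:
    """Inverse of :func:`bar_circle` (identity when the angle is defined)."""
    iso = SymTensor2(bc.dilation_rate, 0.0, bc.dilation_rate)
    if not bc.angle_defined or bc.ce_amplitude == 0.0:
        return iso
    c, s = np.cos(2 * bc.ce_angle), np.sin(2 * bc.ce_angle)
    return iso + bc.ce_amplitude * SymTensor2(c, s, -c)


def alignment_coefficient(field1: TensorField, field2: TensorField) -> float:
    """Weighted alignment of two tensor fields on the same grid, in [-1, 1].

    Returns the weight- and amplitude-weighted average of cos(2*dtheta):
    +1 when the tensors are everywhere parallel, -1 everywhere perpendicular.
    NaN when every norm product vanishes.
    """
    if len(field1) != len(field2) or np.any(field1.m != field2.m) or np.any(
        field1.n != field2.n
    ):
        raise ValueError("fields must share the same (m, n) grid")
    w = np.minimum(field1.weights, field2.weights)
    c1, c2 = field1.components, field2.components
    prods = (c1[:, 0] * c2[:, 0] + 2 * c1[:, 1] * c2[:, 1] + c1[:, 2] * c2[:, 2]) / DIM
    n1 = np.sqrt((c1[:, 0] ** 2 + 2 * c1[:, 1] ** 2 + c1[:, 2] ** 2) / DIM)
    n2 = np.sqrt((c2[:, 0] ** 2 + 2 * c2[:, 1] ** 2 + c2[:, 2] ** 2) / DIM)
    denom = float(np.sum(w * n1 * n2))
    if denom == 0.0:
        return np.nan
    return float(np.sum(w * prods) / denom)


# ---------------------------------------------------------------------------
# projection onto the local morphogenesis axis
# ---------------------------------------------------------------------------

def unit_direction(g: SymTensor2) -> SymTensor2:
    """Unit tensor uG = G/|G| along G; raises on a zero tensor."""
    n = tensor_norm(g)
    if n <= ANGLE_TOL:
        raise ZeroDivisionError("cannot normalize a zero-norm tensor")
    return g / n

def project_component(p: SymTensor2, g: SymTensor2) -> float:
    """Component of P parallel to G: P// = P . uG  (h^-1 for rates).

    For a deviatoric P this is |P| cos(2*dtheta); the components of tensors
    summing to G themselves sum to G// = |G|.  Returns NaN when G has zero
    norm (the component is then undefined, not zero).
    """
    n = tensor_norm(g)
    if n <= ANGLE_TOL:
        return np.nan
    return scalar_product(p, g) / n
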