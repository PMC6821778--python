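"""Four-parameter psychometric function in the bias / discrimination-sensitivity
parameterization used for binocular-rivalry dominance curves.

The curve maps the contrast ``x`` of the manipulated grating (the fixed grating
sits at a constant contrast) onto the expected dominance of the manipulated
percept::

    psi(x) = g + (1 - g - lam) * F(x; u, s)

where ``F`` is an inner sigmoid, ``g`` the guess rate (lower asymptote), ``lam``
the lapse rate (1 - upper asymptote), ``u`` the *bias* (contrast at which the
inner sigmoid crosses dominance 0.5) and ``v`` the *discrimination sensitivity*
(contrast span of the inner sigmoid between dominance 0.25 and 0.75; smaller
span = steeper curve = higher sensitivity).  By default ``F`` is the logistic
function, for which the 0.25-0.75 span fixes the scale as ``s = v / (2 ln 3)``;
a cumulative-Gaussian inner sigmoid (``s = v / (2 * Phi^-1(0.75))``) is
available as an alternative.

Condition differences are parameterized symmetrically: the congruent-imagery
condition (imagining the manipulated grating) uses ``u - delta_u/2`` and the
incongruent condition ``u + delta_u/2``, so ``delta_u > 0`` means less contrast
is needed under congruent imagery — a priming effect — and ``delta_u < 0`` an
adaptation effect.  Likewise ``delta_v > 0`` means a smaller (more sensitive)
contrast span under congruent imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, ndtri

__all__ = [
    "PsychometricParams",
    "ConditionDeltas",
    "evaluate",
    "invert",
    "condition_params",
    "scale_from_sensitivity",
]

#: contrast span -> sigmoid scale conversion constants
_LOGISTIC_SPAN = 2.0 * math.log(3.0)          # logit(0.75) - logit(0.25)
_GAUSSIAN_SPAN = 2.0 * float(ndtri(0.75))     # Phi^-1(0.75) - Phi^-1(0.25)

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONDITIONS = (CONGRUENT, INCONGRUENT)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of one psychometric curve.

    Attributes
    ----------
    u : float
        Bias — contrast at dominance 0.5 of the inner sigmoid (contrast units).
    v : float
        Discrimination sensitivity — contrast span from 0.25 to 0.75 dominance
        of the inner sigmoid; must be positive.
    g : float
        Guess rate (lower asymptote of the full curve).
    lam : float
        Lapse rate (1 minus the upper asymptote).
    sigmoid : str
        Inner sigmoid family, ``"logistic"`` (default) or ``"gaussian"``.
    """

    u: float
    v: float
    g: float = 0.0
    lam: float = 0.0
    sigmoid: str = "logistic"

    def __post_init__(self) -> None:
        if not np.isfinite([self.u, self.v, self.g, self.lam]).all():
            raise ValueError("psychometric parameters must be finite")
        if self.v <= 0:
            raise ValueError(f"discrimination sensitivity v must be > 0, got {self.v}")
        if self.g < 0 or self.lam < 0 or self.g + self.lam >= 1:
            raise ValueError(
                f"require g >= 0, lam >= 0, g + lam < 1; got g={self.g}, lam={self.lam}"
            )
        if self.sigmoid not in ("logistic", "gaussian"):
            raise ValueError(f"unknown sigmoid family {self.sigmoid!r}")


@dataclass(frozen=True)
class ConditionDeltas:
    """Condition differences (incongruent minus congruent) in bias and span.

    ``delta_u > 0`` = priming, ``delta_v > 0`` = congruent sensitization.
    """

    delta_u: float = 0.0
    delta_v: float = 0.0


def scale_from_sensitivity(v, sigmoid: str = "logistic"):
    """Convert the 0.25-0.75 contrast span ``v`` to the sigmoid scale ``s``."""
    span = _LOGISTIC_SPAN if sigmoid == "logistic" else _GAUSSIAN_SPAN
    return np.asarray(v) / span


def evaluate(contrast, params: PsychometricParams):
    """Evaluate the psychometric curve psi at ``contrast``.

    Contrast may be a scalar or array; values outside [0, 1] are allowed (the
    curve is defined on the whole real line, useful for plotting asymptotes).
    Returns dominance strictly inside (g, 1 - lam).
    """
    x = np.asarray(contrast, dtype=float)
    s = scale_from_sensitivity(params.v, params.sigmoid)
    z = (x - params.u) / s
    if params.sigmoid == "logistic":
        inner = expit(z)
    else:
        from scipy.special import ndtr

        inner = ndtr(z)
    out = params.g + (1.0 - params.g - params.lam) * inner
    return out if out.shape else float(out)


def invert(dominance, params: PsychometricParams):
    """Contrast at which the curve reaches ``dominance``.

    ``dominance`` must lie strictly between the asymptotes ``g`` and
    ``1 - lam``; outside that open interval the curve never attains the value.
    """
    d = np.asarray(dominance, dtype=float)
    if np.any(d <= params.g) or np.any(d >= 1.0 - params.lam):
        raise ValueError(
            f"dominance must lie strictly in ({params.g}, {1.0 - params.lam})"
        )
    p = (d - params.g) / (1.0 - params.g - params.lam)
    s = scale_from_sensitivity(params.v, params.sigmoid)
    if params.sigmoid == "logistic":
        z = logit(p)
    else:
        z = ndtri(p)
    out = params.u + s * z
    return out if out.shape else float(out)


def condition_params(
    params: PsychometricParams, deltas: ConditionDeltas, condition: str
) -> PsychometricParams:
    """Apply the symmetric condition offsets to a base parameter set.

    The base (u, v) is the midpoint of the two conditions; guess and lapse
    rates are shared.  Congruent imagery gets ``u - delta_u/2`` and
    ``v - delta_v/2``, incongruent the mirror image.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    sign = -1.0 if condition == CONGRUENT else 1.0
    u_c = params.u + sign * deltas.delta_u / 2.0
    v_c = params.v + sign * deltas.delta_v / 2.0
    if v_c <= 0:
        raise ValueError(
            f"delta_v={deltas.delta_v} drives v non-positive ({v_c}) for {condition}"
        )
    return PsychometricParams(u_c, v_c, params.g, params.lam, params.sigmoid)
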