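"""Exponential-family plumbing for random-intercept GLMMs.

Two families are supported: gaussian with the identity link and binomial
with the logit link.  Penalized quasi-likelihood (PQL) turns a GLMM into a
sequence of weighted linear mixed models through the usual IRLS
linearization; :func:`working_response` is that linearization.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy.special import expit

# Lower clip on binomial mean; keeps working responses finite.
PROB_CLIP = 1e-6


class Family(str, enum.Enum):
    """GLMM response family (link is canonical and implied)."""

    gaussian = "gaussian_identity"
    binomial = "binomial_logit"

    @classmethod
    def coerce(cls, value: "Family | str") -> "Family":
        if isinstance(value, cls):
            return value
        aliases = {
            "gaussian": cls.gaussian,
            "gaussian_identity": cls.gaussian,
            "normal": cls.gaussian,
            "binomial": cls.binomial,
            "binomial_logit": cls.binomial,
            "logistic": cls.binomial,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown family: {value!r}") from None


def working_response(
    outcome: np.ndarray, linear_predictor: np.ndarray, family: Family | str
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS working response ``z`` and weights ``w`` at a linearization point.

    For the gaussian identity link the linearization is exact: ``z = y`` and
    ``w = 1`` regardless of the linear predictor.  For the binomial logit
    link, with ``mu = expit(eta)`` clipped to ``[PROB_CLIP, 1 - PROB_CLIP]``,

    .. math:: z = \\eta + (y - \\mu)/(\\mu(1-\\mu)), \\qquad w = \\mu(1-\\mu).

    Parameters
    ----------
    outcome
        Response values; must be 0/1 for the binomial family.
    linear_predictor
        Current ``eta`` per observation; must be finite.
    family
        ``Family.gaussian`` or ``Family.binomial``.

    Returns
    -------
    (z, w)
        Working values and weights, same shape as ``outcome``.
    """
    family = Family.coerce(family)
    y = np.asarray(outcome, dtype=float)
    eta = np.broadcast_to(np.asarray(linear_predictor, dtype=float), y.shape)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor contains non-finite values")
    if family is Family.gaussian:
        return y.copy(), np.ones_like(y)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("binomial outcome must be coded 0/1")
    mu = np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)
    w = mu * (1.0 - mu)
    z = eta + (y - mu) / w
    return z, w
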