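"""Model parameters and prior hyperparameters.

The generative model has two characteristic saccade length scales: a
*local* diagonal Gaussian covariance ``(eps_x, eps_y)`` (short saccades,
px^2) and a *global* covariance ``(xi_x, xi_y)`` (long, saliency-driven
saccades, px^2), with the global scale strictly larger on each axis.
The choice between the two modes is driven by a logistic link with slope
``b`` and offset ``s_o``; the ``fixed_choice`` variant replaces the link
by a constant mixing probability ``rho_fixed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

VARIANTS = (
    "full",
    "local_choice",
    "fixed_choice",
    "local_saliency",
    "saliency_baseline",
)

#: variants whose step distribution mixes a local and a global component
MIXTURE_VARIANTS = ("full", "local_choice", "fixed_choice")

#: floor applied to the denominator saliency value in the ratio link;
#: saliency maps sum to one, so this is 1e-12 of the total map mass
RATIO_FLOOR = 1e-12

#: floor applied to per-step probabilities before taking logs
LOGLIK_FLOOR = 1e-300


class DegenerateGlobalMapError(ValueError):
    """Raised when the clamped global attention map has zero total mass."""


@dataclass
class ModelParams:
    """Parameters Theta of the scan-path model (one variant thereof).

    All length scales are variances in squared pixels.
    """

    eps_x: float = 25.0
    eps_y: float = 25.0
    xi_x: float = 2500.0
    xi_y: float = 2500.0
    b: float = 1.0
    s_o: float = 1.0
    variant: str = "full"
    rho_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.variant == "saliency_baseline":
            return
        for name in ("xi_x", "xi_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.variant == "local_saliency":
            return
        for name in ("eps_x", "eps_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.xi_x > self.eps_x and self.xi_y > self.eps_y):
            raise ValueError(
                "global covariance must dominate the local one: "
                f"xi=({self.xi_x}, {self.xi_y}) vs eps=({self.eps_x}, {self.eps_y})"
            )
        if self.variant == "fixed_choice":
            if self.rho_fixed is None or not 0.0 <= self.rho_fixed <= 1.0:
                raise ValueError("fixed_choice requires rho_fixed in [0, 1]")

    @property
    def has_global(self) -> bool:
        return self.variant in MIXTURE_VARIANTS

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "eps_x": self.eps_x,
            "eps_y": self.eps_y,
            "xi_x": self.xi_x,
            "xi_y": self.xi_y,
            "b": self.b,
            "s_o": self.s_o,
        }
        if self.rho_fixed is not None:
            d["rho_fixed"] = self.rho_fixed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class Hyperparams:
    """Prior hyperparameters (conjugate family).

    Scales carry Inverse-Gamma(shape, scale) priors, the link parameters
    Gaussian priors, and ``rho_fixed`` a Beta prior.  The defaults induce
    wide priors spanning the range of typical human saccade amplitudes
    (roughly 0.5 to 40 degrees of visual angle; at the package's default
    4 px/degree that is ~2 to 160 px, i.e. variances of ~4 to 2.5e4 px^2).
    The same shape/scale is used for the x and y axis of each covariance.
    """

    alpha_eps: float = 2.0
    beta_eps: float = 25.0
    alpha_xi: float = 2.0
    beta_xi: float = 2500.0
    mu_b: float = 0.0
    sigma_b: float = 5.0
    mu_so: float = 0.0
    sigma_so: float = 5.0
    beta_a: float = 1.0
    beta_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_eps", "beta_eps", "alpha_xi", "beta_xi",
                     "sigma_b", "sigma_so", "beta_a", "beta_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def default_for_data(cls, mean_design: float, **overrides) -> "Hyperparams":
        """Data-dependent default: centre the link priors on the scale of the
        average design value (saliency ratio, or saliency value for the
        local_choice variant) observed in the data."""
        scale = max(abs(float(mean_design)), 1.0)
        base = dict(mu_so=float(mean_design), sigma_so=5.0 * scale,
                    mu_b=0.0, sigma_b=5.0)
        base.update(overrides)
        return cls(**base)
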