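"""Model parameters.

Angles are in degrees, times in milliseconds, learning rates per second,
coefficients dimensionless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the four-population remapping network.

    Defaults reproduce the reference configuration: 91 visual neurons on the
    integer grid [-45, 45] deg, 61 saccade neurons on [-30, 30] deg, 1000
    combination neurons, and 91 remapping neurons on [-45, 45] deg.

    ``n_R`` defaults to 91 (one neuron per integer retinal location). Larger
    values are supported and assign retinal preferences cyclically over the
    91 integer locations.
    """

    # population sizes
    n_V: int = 91
    n_S: int = 61
    n_C: int = 1000
    n_R: int = 91
    # time constants (ms)
    tau_v_V: float = 1000.0
    tau_v_S: float = 20.0
    tau_h_C: float = 20.0
    tau_h_R: float = 20.0
    tau_K: float = 20.0
    tau_P: float = 300.0
    # tuning widths (deg)
    sigma_V: float = 3.0
    sigma_S: float = 3.0
    sigma_R: float = 3.0
    # delays (ms)
    delta_V: float = 280.0          # visual post-saccadic suppression delay
    delta_S_pre: float = 70.0       # saccade-pop pre-saccadic onset lead
    delta_S_post: float = 300.0     # saccade-pop post-saccadic offset delay
    delta_K: float = 0.0            # K/P truncation delay after saccade onset
    # input coefficients
    psi_VC: float = 10.0
    psi_SC: float = 8.0
    psi_CR: float = 3.0
    psi_K: float = 8.0
    # lateral inhibition
    w_inhb_C: float = 0.1
    w_inhb_R: float = 0.6
    # sigmoid nonlinearities
    slope_C: float = 100.0
    theta_C: float = 15.0
    slope_R: float = 0.5
    theta_R: float = 3.0
    # learning rates
    rho_VC: float = 0.1
    rho_SC: float = 0.1
    rho_CR: float = 0.1
    # connectivity fractions
    phi_V: float = 0.05
    phi_S: float = 0.20
    phi_C: float = 1.0
    # onset-delay distribution of the remapping visual drive (ms)
    gamma_sd: float = 50.0
    gamma_clip: float = 80.0
    # kinematics
    saccade_speed: float = 300.0    # deg/s, constant-velocity saccades
    # training protocol
    M: int = 17
    epochs: int = 20

    def __post_init__(self) -> None:
        for name in ("tau_v_V", "tau_v_S", "tau_h_C", "tau_h_R", "tau_K",
                     "tau_P", "sigma_V", "sigma_S", "sigma_R", "rho_VC",
                     "rho_SC", "rho_CR", "saccade_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("phi_V", "phi_S", "phi_C"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("delta_V", "delta_S_pre", "delta_S_post", "delta_K",
                     "gamma_sd", "gamma_clip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build from a config mapping; unknown keys are an error."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_config(cls, path: str) -> "ModelParams":
        """Read parameters from a YAML (or JSON) config file."""
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config {path!r} must contain a mapping")
        return cls.from_dict(d)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the parameter values, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
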