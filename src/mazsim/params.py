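"""Kinetic parameters, stress protocols and growth coupling for the mazEF module.

The mazEF type II toxin-antitoxin operon encodes the labile antitoxin MazE
(degraded by ClpAP/Lon) and the stable endoribonuclease toxin MazF, which
cleaves single-stranded RNA at ACA sites -- including its own polycistronic
transcript.  All tunable constants of the stochastic model live in the three
dataclasses below; every field is overridable through a YAML config file.

Units: time in minutes, rates in 1/min, lengths in micrometres, molecule
numbers are dimensionless counts.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

import yaml

from .errors import ParameterError


class StressMode(enum.Enum):
    """How an episode of stress is imposed on the module.

    ANTITOXIN_DEGRADATION multiplies the MazE proteolysis rate inside the
    stress window (upregulated ClpAP/Lon under nutritional stress);
    TOXIN_PRODUCTION switches on ectopic toxin-only transcription inside the
    window (arabinose induction of a pBAD-borne toxin gene).
    """

    ANTITOXIN_DEGRADATION = "antitoxin_degradation"
    TOXIN_PRODUCTION = "toxin_production"


class OperatorState(enum.IntEnum):
    """Occupancy of the single chromosomal mazEF operator.

    Conditional cooperativity is realized with four discrete states: the
    free operator transcribes at full rate, antitoxin- or complex-bound
    states are repressed, and a second toxin on the bound complex (O_CT)
    de-represses by rapidly ejecting the whole assembly.
    """

    FREE = 0
    O_A = 1
    O_C = 2
    O_CT = 3


@dataclass
class KineticParams:
    """Rate constants of the mazEF reaction network.

    Defaults give fast antitoxin turnover, a stable toxin, a translational
    excess of antitoxin over toxin, and a 9:2 toxin-region:antitoxin-region
    cleavage weighting reflecting the ACA-site counts of the two cistrons.
    """

    k_tx: float = 2.0            # transcription initiation from free operator
    alpha_OA: float = 0.1        # residual transcription, antitoxin-bound operator
    alpha_OC: float = 0.02       # residual transcription, complex-bound operator
    alpha_OCT: float = 1.0       # residual transcription, complex+toxin-bound
    b_A: float = 3.0             # antitoxin translation per transcript
    b_T: float = 0.1             # toxin translation per transcript
    delta_A: float = 0.2         # antitoxin proteolysis
    delta_T: float = 0.005       # toxin degradation (toxin is nearly stable)
    delta_m: float = 0.2         # basal mRNA decay
    k_cleave: float = 2.0        # MazF cleavage per (free toxin, transcript) pair
    w_E: float = 2.0             # antitoxin-region cleavage weight (ACA count)
    w_F: float = 9.0             # toxin-region cleavage weight (ACA count)
    kon: float = 100.0           # toxin-antitoxin association (fast neutralization)
    koff: float = 0.01           # complex dissociation
    kb_A: float = 0.03           # operator binding by antitoxin (per molecule)
    ku_A: float = 1.0            # operator release of antitoxin
    kb_C: float = 0.03           # operator binding by complex (per molecule)
    ku_C: float = 1.0            # operator release of complex
    kb_T2: float = 0.1           # second toxin binding the operator-bound complex
    ku_T2: float = 10.0          # fast ejection of the complex+toxin assembly
    beta_ect: float = 0.85       # ectopic toxin-only transcription when induced
    cleavable_ect: bool = True   # False models a recoded (ACA-free) ectopic gene

    _RATE_FIELDS = (
        "k_tx", "b_A", "b_T", "delta_A", "delta_T", "delta_m", "k_cleave",
        "kon", "koff", "kb_A", "ku_A", "kb_C", "ku_C", "kb_T2", "ku_T2",
        "beta_ect",
    )

    def validate(self) -> "KineticParams":
        for name in self._RATE_FIELDS:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ParameterError(name, f"rate must be >= 0, got {v!r}")
        for name in ("alpha_OA", "alpha_OC", "alpha_OCT"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(name, f"must lie in [0, 1], got {v!r}")
        for name in ("w_E", "w_F"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ParameterError(name, f"cleavage weight must be > 0, got {v!r}")
        if not (self.delta_A > self.delta_T):
            raise ParameterError(
                "delta_A",
                "antitoxin must be less stable than toxin "
                f"(delta_A={self.delta_A} <= delta_T={self.delta_T})",
            )
        return self

    def replace(self, **kwargs) -> "KineticParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StressProtocol:
    """A single stress window [t_on, t_off) applied in one of two modes."""

    mode: StressMode = StressMode.ANTITOXIN_DEGRADATION
    multiplier: float = 3.0
    t_on: float = 360.0
    t_off: float = 720.0

    def validate(self) -> "StressProtocol":
        if isinstance(self.mode, str):
            self.mode = StressMode(self.mode)
        if not (self.t_on < self.t_off):
            raise ParameterError("t_on", f"need t_on < t_off, got [{self.t_on}, {self.t_off})")
        if not (self.multiplier >= 1.0):
            raise ParameterError("multiplier", f"must be >= 1, got {self.multiplier!r}")
        return self

    def in_window(self, t: float) -> bool:
        return self.t_on <= t < self.t_off

    def delta_A_factor(self, t: float) -> float:
        if self.mode is StressMode.ANTITOXIN_DEGRADATION and self.in_window(t):
            return self.multiplier
        return 1.0

    def ect_active(self, t: float) -> bool:
        return self.mode is StressMode.TOXIN_PRODUCTION and self.in_window(t)

    def replace(self, **kwargs) -> "StressProtocol":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GrowthCoupling:
    """Couples free toxin to cell elongation and reporter production.

    Elongation follows dL/dt = g(D) L with the Hill inhibition
    g(D) = g_max / (1 + (D/K_g)^h_g), where D is the translational damage
    level: a low-pass filter of the free-toxin count,
    dD/dt = (T - D) / tau_g.  The filter captures that MazF injures the
    translation machinery (rRNA precursors, stressed ribosomes) and that
    capacity recovers over tens of minutes after the free toxin is
    neutralized; tau_g -> 0 recovers an instantaneous g(T) response.
    The constitutive stable reporter is produced at p_max/(1+(T/K_p)^h_p)
    per minute; reporter production is inhibited more weakly than growth
    (K_p >> K_g), so its concentration R/L rises when growth is hit harder
    than protein synthesis -- the reporter-dilution proxy for growth rate.
    """

    g_max: float = 0.0231        # 1/min; doubling time ln2/g_max ~ 30 min
    K_g: float = 8.0             # damage level halving elongation
    h_g: float = 4.0
    tau_g: float = 30.0          # min; translational-damage relaxation time
    p_max: float = 20.0          # reporter molecules per minute, uninhibited
    K_p: float = 100.0
    h_p: float = 1.0
    L_div: float = 4.0           # sizer division threshold, micrometres
    L_birth0: float = 2.0        # founder birth length
    div_rate: float = 20.0       # 1/min; division rate once past the threshold
    K_d: float = 1.5             # damage level halving the division rate
    h_d: float = 4.0
    div_cv: float = 0.02         # CV of the per-cycle sizer threshold

    def validate(self) -> "GrowthCoupling":
        for name in ("g_max", "K_g", "p_max", "K_p", "L_div", "L_birth0",
                     "div_rate", "K_d"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ParameterError(name, f"must be > 0, got {v!r}")
        if self.tau_g < 0:
            raise ParameterError("tau_g", "damage relaxation time must be >= 0")
        if self.div_cv < 0:
            raise ParameterError("div_cv", "threshold CV must be >= 0")
        for name in ("h_g", "h_p", "h_d"):
            v = getattr(self, name)
            if not (v >= 1.0):
                raise ParameterError(name, f"Hill exponent must be >= 1, got {v!r}")
        return self

    def growth_rate(self, damage: float) -> float:
        return self.g_max / (1.0 + (damage / self.K_g) ** self.h_g)

    def reporter_rate(self, T: float) -> float:
        return self.p_max / (1.0 + (T / self.K_p) ** self.h_p)

    def replace(self, **kwargs) -> "GrowthCoupling":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimConfig:
    """Bundle of everything a simulation run needs, YAML round-trippable."""

    params: KineticParams = field(default_factory=KineticParams)
    protocol: StressProtocol = field(default_factory=StressProtocol)
    coupling: GrowthCoupling = field(default_factory=GrowthCoupling)
    include_cleavage: bool = True
    burn_in: float = 180.0       # minutes of pre-time-zero growth discarded
    t_end: float = 900.0
    n_cells: int = 500
    seed: int = 0

    def validate(self) -> "SimConfig":
        self.params.validate()
        self.protocol.validate()
        self.coupling.validate()
        if self.burn_in < 0:
            raise ParameterError("burn_in", "must be >= 0")
        if self.t_end <= 0:
            raise ParameterError("t_end", "must be > 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells", "must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "protocol": dataclasses.asdict(self.protocol),
            "coupling": dataclasses.asdict(self.coupling),
            "include_cleavage": self.include_cleavage,
            "burn_in": self.burn_in,
            "t_end": self.t_end,
            "n_cells": self.n_cells,
            "seed": self.seed,
        }
        d["protocol"]["mode"] = self.protocol.mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d or {})
        params = KineticParams(**d.pop("params", {}))
        proto = d.pop("protocol", {})
        if "mode" in proto:
            proto["mode"] = StressMode(proto["mode"])
        protocol = StressProtocol(**proto)
        coupling = GrowthCoupling(**d.pop("coupling", {}))
        return cls(params=params, protocol=protocol, coupling=coupling, **d).validate()

    def dump(self, stream: Optional[TextIO] = None) -> Optional[str]:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def load(cls, source: Union[str, TextIO]) -> "SimConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)
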