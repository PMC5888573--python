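"""Reaction network and exact stochastic simulation of the mazEF module.

Species of a single cell:

==========  ===================================================================
``m_EF``    full-length polycistronic mazEF transcripts (both cistrons intact)
``m_E``     toxin-region-cleaved transcripts that still translate antitoxin
``m_ect``   ectopic toxin-only transcripts (arabinose-induced construct)
``A``       free antitoxin (MazE-like, labile)
``T``       free toxin (MazF-like, stable endoribonuclease)
``C``       neutralized antitoxin-toxin complex
``op``      operator occupancy: FREE, O_A, O_C or O_CT
==========  ===================================================================

Transcriptional negative autoregulation is realized through the four operator
states (conditional cooperativity: repression is maximal at moderate
toxin:antitoxin ratios, a second toxin on the bound complex de-represses).
Post-transcriptional positive feedback enters through toxin-catalysed
transcript cleavage: the toxin-encoding region carries ``w_F`` cleavage sites
against ``w_E`` in the antitoxin region, so the toxin-region channel fires
``w_F / w_E`` times more often.  Toxin-region cleavage leaves an
antitoxin-translating fragment; antitoxin-region cleavage inactivates the
transcript entirely.

The simulator is the exact direct (Gillespie) method.  The stress protocol
makes propensities piecewise-constant in time; exactness is preserved by
treating the window bounds ``t_on``/``t_off`` as hard event horizons at which
the waiting time is re-drawn (valid by memorylessness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MazsimError, ParameterError, StateError
from .params import KineticParams, OperatorState, StressProtocol

#: order of the count species in state vectors
SPECIES = ("m_EF", "m_E", "m_ect", "A", "T", "C")
#: index of the operator-state slot in a 7-long state vector
OP_INDEX = 6


@dataclass
class SpeciesState:
    """Integer molecular state of one cell."""

    m_EF: int = 0
    m_E: int = 0
    m_ect: int = 0
    A: int = 0
    T: int = 0
    C: int = 0
    op_state: OperatorState = OperatorState.FREE

    def validate(self) -> "SpeciesState":
        for name in SPECIES:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise StateError(f"count {name} must be a non-negative integer, got {v!r}")
        if not isinstance(self.op_state, OperatorState):
            self.op_state = OperatorState(self.op_state)
        return self

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.m_EF, self.m_E, self.m_ect, self.A, self.T, self.C, int(self.op_state)],
            dtype=np.int64,
        )

    @classmethod
    def from_vector(cls, vec: Sequence[int]) -> "SpeciesState":
        return cls(
            m_EF=int(vec[0]), m_E=int(vec[1]), m_ect=int(vec[2]),
            A=int(vec[3]), T=int(vec[4]), C=int(vec[5]),
            op_state=OperatorState(int(vec[6])),
        )

    @property
    def total_toxin(self) -> int:
        """Free + complexed + operator-sequestered toxin (1 in O_C, 2 in O_CT)."""
        extra = {OperatorState.FREE: 0, OperatorState.O_A: 0,
                 OperatorState.O_C: 1, OperatorState.O_CT: 2}[self.op_state]
        return self.T + self.C + extra

    @property
    def total_antitoxin(self) -> int:
        """Free + complexed + operator-sequestered antitoxin."""
        extra = 0 if self.op_state is OperatorState.FREE else 1
        return self.A + self.C + extra

    def replace(self, **kwargs) -> "SpeciesState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: stoichiometry plus a propensity function.

    ``delta`` changes the six molecular counts; operator transitions are
    encoded by ``op_from``/``op_to`` (the propensity is zero unless the
    operator is in ``op_from``).
    """

    name: str
    delta: Tuple[int, int, int, int, int, int]
    rate: Callable[[np.ndarray, float, StressProtocol], float]
    op_from: Optional[OperatorState] = None
    op_to: Optional[OperatorState] = None

    def propensity(self, vec: np.ndarray, t: float, protocol: StressProtocol) -> float:
        if self.op_from is not None and vec[OP_INDEX] != int(self.op_from):
            return 0.0
        return self.rate(vec, t, protocol)

    def apply(self, vec: np.ndarray) -> None:
        vec[:6] += self.delta
        if self.op_to is not None:
            vec[OP_INDEX] = int(self.op_to)


class ReactionSet:
    """Ordered reaction list for one parameterization of the module."""

    def __init__(self, params: KineticParams, include_cleavage: bool):
        self.params = params
        self.include_cleavage = bool(include_cleavage)
        self.reactions: List[Reaction] = _build_reactions(params, include_cleavage)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def names(self) -> List[str]:
        return [r.name for r in self.reactions]

    def propensities(self, state: SpeciesState, t: float, protocol: StressProtocol) -> np.ndarray:
        state.validate()
        vec = state.to_vector()
        return self.propensity_vector(vec, t, protocol)

    def propensity_vector(self, vec: np.ndarray, t: float, protocol: StressProtocol) -> np.ndarray:
        if (vec[:6] < 0).any():
            bad = [SPECIES[i] for i in np.nonzero(vec[:6] < 0)[0]]
            raise StateError(f"negative counts for {bad}")
        a = np.empty(len(self.reactions))
        for i, r in enumerate(self.reactions):
            ai = r.propensity(vec, t, protocol)
            if not math.isfinite(ai) or ai < 0:
                raise MazsimError(f"non-finite/negative propensity for reaction {r.name!r}: {ai}")
            a[i] = ai
        return a


F = OperatorState.FREE
OA = OperatorState.O_A
OC = OperatorState.O_C
OCT = OperatorState.O_CT


def _build_reactions(p: KineticParams, include_cleavage: bool) -> List[Reaction]:
    alpha = {F: 1.0, OA: p.alpha_OA, OC: p.alpha_OC, OCT: p.alpha_OCT}
    frac_F = p.w_F / (p.w_E + p.w_F)
    frac_E = p.w_E / (p.w_E + p.w_F)
    rxns = [
        Reaction("transcribe_mEF", (1, 0, 0, 0, 0, 0),
                 lambda v, t, pr, a=alpha: p.k_tx * a[OperatorState(int(v[OP_INDEX]))]),
        Reaction("transcribe_ect", (0, 0, 1, 0, 0, 0),
                 lambda v, t, pr: p.beta_ect if pr.ect_active(t) else 0.0),
        Reaction("translate_A", (0, 0, 0, 1, 0, 0),
                 lambda v, t, pr: p.b_A * (v[0] + v[1])),
        Reaction("translate_T", (0, 0, 0, 0, 1, 0),
                 lambda v, t, pr: p.b_T * (v[0] + v[2])),
        Reaction("decay_mEF", (-1, 0, 0, 0, 0, 0), lambda v, t, pr: p.delta_m * v[0]),
        Reaction("decay_mE", (0, -1, 0, 0, 0, 0), lambda v, t, pr: p.delta_m * v[1]),
        Reaction("decay_mect", (0, 0, -1, 0, 0, 0), lambda v, t, pr: p.delta_m * v[2]),
        Reaction("degrade_A", (0, 0, 0, -1, 0, 0),
                 lambda v, t, pr: p.delta_A * pr.delta_A_factor(t) * v[3]),
        Reaction("degrade_T", (0, 0, 0, 0, -1, 0), lambda v, t, pr: p.delta_T * v[4]),
        Reaction("bind_AT", (0, 0, 0, -1, -1, 1), lambda v, t, pr: p.kon * v[3] * v[4]),
        Reaction("unbind_C", (0, 0, 0, 1, 1, -1), lambda v, t, pr: p.koff * v[5]),
        # proteolysis of the antitoxin inside the complex frees the toxin;
        # this is the step that converts antitoxin loss into free-toxin gain
        Reaction("degrade_A_in_C", (0, 0, 0, 0, 1, -1),
                 lambda v, t, pr: p.delta_A * pr.delta_A_factor(t) * v[5]),
        Reaction("degrade_T_in_C", (0, 0, 0, 1, 0, -1),
                 lambda v, t, pr: p.delta_T * v[5]),
        Reaction("op_bind_A", (0, 0, 0, -1, 0, 0),
                 lambda v, t, pr: p.kb_A * v[3], op_from=F, op_to=OA),
        Reaction("op_unbind_A", (0, 0, 0, 1, 0, 0),
                 lambda v, t, pr: p.ku_A, op_from=OA, op_to=F),
        Reaction("op_bind_C", (0, 0, 0, 0, 0, -1),
                 lambda v, t, pr: p.kb_C * v[5], op_from=F, op_to=OC),
        Reaction("op_unbind_C", (0, 0, 0, 0, 0, 1),
                 lambda v, t, pr: p.ku_C, op_from=OC, op_to=F),
        Reaction("op_bind_T2", (0, 0, 0, 0, -1, 0),
                 lambda v, t, pr: p.kb_T2 * v[4], op_from=OC, op_to=OCT),
        # fast ejection of the whole complex+toxin assembly: de-repression
        # at high toxin:antitoxin ratio (conditional cooperativity)
        Reaction("op_eject_CT", (0, 0, 0, 0, 1, 1),
                 lambda v, t, pr: p.ku_T2, op_from=OCT, op_to=F),
    ]
    if include_cleavage:
        rxns += [
            Reaction("cleave_F_mEF", (-1, 1, 0, 0, 0, 0),
                     lambda v, t, pr: p.k_cleave * v[4] * v[0] * frac_F),
            Reaction("cleave_E_mEF", (-1, 0, 0, 0, 0, 0),
                     lambda v, t, pr: p.k_cleave * v[4] * v[0] * frac_E),
            Reaction("cleave_E_mE", (0, -1, 0, 0, 0, 0),
                     lambda v, t, pr: p.k_cleave * v[4] * v[1] * frac_E),
        ]
        if p.cleavable_ect:
            rxns.append(
                Reaction("cleave_F_mect", (0, 0, -1, 0, 0, 0),
                         lambda v, t, pr: p.k_cleave * v[4] * v[2] * frac_F))
    return rxns


def build_network(params: KineticParams, include_cleavage: bool = True) -> ReactionSet:
    """Assemble the mazEF reaction network.

    With ``include_cleavage=False`` all toxin-catalysed mRNA cleavage
    channels are absent and the remaining network is identical
    reaction-for-reaction.
    """
    params.validate()
    return ReactionSet(params, include_cleavage)


def propensities(state: SpeciesState, params: KineticParams, t: float,
                 protocol: StressProtocol, include_cleavage: bool = True) -> np.ndarray:
    """Propensity vector of the network at ``(state, t)``."""
    return build_network(params, include_cleavage).propensities(state, t, protocol)


def apply_cleavage_outcome(state: SpeciesState, region: str) -> SpeciesState:
    """State after one toxin-catalysed cleavage of a full-length transcript.

    Cleavage in the toxin-encoding region (``"F"``) leaves a fragment that
    still translates antitoxin; cleavage in the antitoxin-encoding region
    (``"E"``) inactivates the transcript.  The toxin acts catalytically.
    """
    state.validate()
    if state.m_EF < 1:
        raise StateError("apply_cleavage_outcome requires m_EF >= 1")
    if region == "F":
        return state.replace(m_EF=state.m_EF - 1, m_E=state.m_E + 1)
    if region == "E":
        return state.replace(m_EF=state.m_EF - 1)
    raise ParameterError("region", f"must be 'E' or 'F', got {region!r}")


class Trajectory:
    """Piecewise-constant single-cell trajectory from an exact simulation."""

    def __init__(self, times: np.ndarray, states: np.ndarray, t_end: float):
        self.times = times        # event times, times[0] = t_start
        self.states = states      # (n_events+1, 7) state AFTER each event
        self.t_end = float(t_end)

    def at(self, t) -> np.ndarray:
        """State vector(s) at arbitrary query time(s) in [t_start, t_end]."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.states[idx]

    def species(self, name: str, t) -> np.ndarray:
        i = SPECIES.index(name) if name in SPECIES else OP_INDEX
        return np.asarray(self.at(t))[..., i]

    def final_state(self) -> SpeciesState:
        return SpeciesState.from_vector(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES) + ["op_state"])
        df.insert(0, "time_min", self.times)
        return df


def simulate_cell(init: SpeciesState, params: KineticParams,
                  protocol: StressProtocol, t_end: float, seed: int,
                  include_cleavage: bool = True, t_start: float = 0.0) -> Trajectory:
    """Exact direct-method simulation of one cell's molecular state.

    Identical ``(init, params, protocol, t_end, seed)`` reproduce the exact
    event sequence.  Stress-window bounds are treated as event horizons so
    the piecewise-constant time dependence stays exact.
    """
    if not (t_end > t_start):
        raise ParameterError("t_end", f"must exceed t_start={t_start}, got {t_end}")
    params.validate()
    protocol.validate()
    init.validate()
    network = build_network(params, include_cleavage)
    rng = np.random.default_rng(seed)

    horizons = sorted({h for h in (protocol.t_on, protocol.t_off) if t_start < h < t_end})
    horizons.append(t_end)

    vec = init.to_vector()
    times = [t_start]
    states = [vec.copy()]
    t = t_start
    h_idx = 0
    while t < t_end:
        horizon = horizons[h_idx]
        a = network.propensity_vector(vec, t, protocol)
        a0 = a.sum()
        if a0 <= 0.0:
            t = horizon
        else:
            dt = rng.exponential(1.0 / a0)
            if t + dt >= horizon:
                t = horizon   # no event before the horizon; re-draw beyond it
            else:
                t += dt
                j = np.searchsorted(np.cumsum(a), rng.random() * a0, side="right")
                network.reactions[min(j, len(a) - 1)].apply(vec)
                times.append(t)
                states.append(vec.copy())
                continue
        if t >= horizon and h_idx < len(horizons) - 1:
            h_idx += 1
    return Trajectory(np.array(times), np.array(states), t_end)
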