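"""Synthetic inputs with the statistical structure the analyses assume.

Generates the four input classes the toolkit consumes, so the full pipeline
is testable without any downloads: flow-cytometry-like event tables
(lognormal mixtures on a 4-decade log scale), Schnitzcells-style lineage
tables at 5-min frame sampling, qRT-PCR decay series (target + reference
gene), and random in-frame coding sequences with a controlled number of ACA
sites.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lineage import LINEAGE_COLUMNS
from .transcripts import CodingSequence, find_ACA

_FLOW_RANGE = (1.0, 1.0e4)   # 4 positive decades, flow-channel-like


@dataclass
class MixtureSpec:
    """Lognormal mixture of fluorescence populations (log10 parameterized)."""

    components: Sequence[Tuple[float, float, float]]   # (weight, log10 mean, log10 sd)
    n: int = 10_000
    seed: int = 0

    def validate(self) -> "MixtureSpec":
        if not self.components:
            raise ParameterError("components", "need at least one component")
        w = np.array([c[0] for c in self.components], dtype=float)
        sd = np.array([c[2] for c in self.components], dtype=float)
        if (w <= 0).any() or not np.isclose(w.sum(), 1.0):
            raise ParameterError("components", "weights must be positive and sum to 1")
        if (sd <= 0).any():
            raise ParameterError("components", "log10 sds must be > 0")
        if self.n < 1:
            raise ParameterError("n", "need n >= 1 events")
        return self


def gen_flow_events(spec: MixtureSpec) -> np.ndarray:
    """Draw a flow-cytometry-like event vector from a lognormal mixture,
    clipped to the 4-decade positive range."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[0] for c in spec.components])
    comp = rng.choice(len(weights), size=spec.n, p=weights)
    mu = np.array([c[1] for c in spec.components])[comp]
    sd = np.array([c[2] for c in spec.components])[comp]
    values = 10.0 ** rng.normal(mu, sd)
    return np.clip(values, *_FLOW_RANGE)


@dataclass
class LineageSimSpec:
    """Mother-machine-like lineage generator settings.

    ``growth_rate`` is either a constant (1/min) or a callable g(t); length
    grows exponentially with multiplicative lognormal frame noise and the
    cell divides symmetrically at a noisy sizer threshold.  Total
    fluorescence is concentration x area, with the reporter concentration
    following the inverse-growth coupling ``conc(t) = conc0 * g0 / g(t)``
    (slow growth concentrates the stable reporter).
    """

    growth_rate: Union[float, Callable[[float], float]] = 0.0231
    length_noise_sd: float = 0.02
    frame_interval: float = 5.0
    duration: float = 600.0
    L_birth: float = 2.0
    L_div: float = 4.0
    div_threshold_cv: float = 0.05
    conc0: float = 300.0
    aspect: float = 0.5          # area per unit length (um^2/um), rod geometry
    n_lineages: int = 1
    seed: int = 0

    def validate(self) -> "LineageSimSpec":
        for name in ("frame_interval", "duration", "L_birth", "L_div", "conc0", "aspect"):
            if not (getattr(self, name) > 0):
                raise ParameterError(name, "must be > 0")
        if self.length_noise_sd < 0 or self.div_threshold_cv < 0:
            raise ParameterError("length_noise_sd", "noise parameters must be >= 0")
        if self.n_lineages < 1:
            raise ParameterError("n_lineages", "must be >= 1")
        return self

    def g(self, t: float) -> float:
        return self.growth_rate(t) if callable(self.growth_rate) else float(self.growth_rate)


def gen_lineage(spec: LineageSimSpec) -> pd.DataFrame:
    """Simulate Schnitzcells-style lineage tables (one row per 5-min frame)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g0 = max(spec.g(0.0), 1e-12)
    rows: List[tuple] = []
    for lid in range(spec.n_lineages):
        L = spec.L_birth
        times = np.arange(0.0, spec.duration + 1e-9, spec.frame_interval)
        thresh = spec.L_div * (1.0 + spec.div_threshold_cv * rng.standard_normal())
        for t in times:
            g = spec.g(t)
            conc = spec.conc0 * g0 / max(g, 1e-12)
            area = spec.aspect * L
            division = L >= thresh
            rows.append((t, lid, L, area, conc * area, division))
            if division:
                L = L / 2.0
                thresh = spec.L_div * (1.0 + spec.div_threshold_cv * rng.standard_normal())
            noise = np.exp(spec.length_noise_sd * rng.standard_normal()) \
                if spec.length_noise_sd > 0 else 1.0
            L = L * np.exp(g * spec.frame_interval) * noise
    return pd.DataFrame(rows, columns=list(LINEAGE_COLUMNS))


def gen_qpcr(t_half: float, efficiency: float = 2.0, noise_sd: float = 0.1,
             times: Optional[Sequence[float]] = None, seed: int = 0,
             target: str = "mazF", reference: str = "cysG",
             n_replicates: int = 1, ct0_target: float = 20.0,
             ct0_ref: float = 18.0) -> pd.DataFrame:
    """Simulate a qRT-PCR decay experiment as a tidy Ct table.

    The reference gene is constant in expectation; the target follows exact
    first-order decay with half-life ``t_half`` so its Ct rises by
    ``log_eff(2) * t/t_half``.  Gaussian noise of ``noise_sd`` cycles is
    added to every Ct value.
    """
    if not (t_half > 0):
        raise ParameterError("t_half", "must be > 0")
    if not (1.0 < efficiency <= 2.0):
        raise ParameterError("efficiency", f"must lie in (1, 2], got {efficiency!r}")
    if times is None:
        times = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    lam = np.log(2.0) / t_half
    rows = []
    for rep in range(n_replicates):
        for t in times:
            d_ct = lam * t / np.log(efficiency)   # exact exponential decay
            rows.append((t, target, rep, ct0_target + d_ct
                         + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)))
            rows.append((t, reference, rep, ct0_ref
                         + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)))
    return pd.DataFrame(rows, columns=["time_min", "gene", "replicate", "ct"])


_NON_STOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
_SAFE_CODONS = [c for c in _NON_STOP
                if "ACA" not in c and c != "ACA"
                and not c.startswith("CA")       # X-"ACA" + CA? junction guard
                and not c.endswith("AC")         # ?AC + "A.." junction guard
                and not c.endswith("A")]         # ?A + "CA." junction guard


def gen_cds(length_codons: int, target_ACA_count: int, seed: int = 0,
            id: Optional[str] = None) -> CodingSequence:
    """Random in-frame CDS (ATG start, no internal stops) with exactly the
    requested number of ACA occurrences.

    An ACA-free backbone is sampled from junction-safe codons, then
    ``target_ACA_count`` interior codons are replaced by the Thr codon ACA;
    the generator re-draws until an oracle scan confirms the exact count.
    """
    if length_codons < 2:
        raise ParameterError("length_codons", "need at least start + stop")
    max_sites = length_codons - 2   # interior codons only
    if not (0 <= target_ACA_count <= max_sites):
        raise ParameterError(
            "target_ACA_count",
            f"infeasible: need 0 <= count <= {max_sites} for {length_codons} codons")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        body = list(rng.choice(_SAFE_CODONS, size=length_codons - 2))
        if target_ACA_count > 0:
            sites = rng.choice(len(body), size=target_ACA_count, replace=False)
            for s in sites:
                body[s] = "ACA"
        seq = "ATG" + "".join(body) + "TAA"
        cds = CodingSequence(id=id or f"synthetic_cds_{seed}", nucleotides=seq)
        if len(find_ACA(cds)) == target_ACA_count:
            return cds
    raise ParameterError("target_ACA_count",
                         "could not realize the requested ACA count")
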