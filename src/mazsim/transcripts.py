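"""Sequence-level tools: ACA-site enumeration, protein-preserving recoding,
cleavage-region weights, and mRNA half-life estimation from qRT-PCR decay.

MazF cleaves single-stranded RNA at ACA trinucleotides.  A transcript's
susceptibility therefore scales with its ACA count, and a coding sequence can
be made cleavage-immune by swapping synonymous codons until no ACA remains
(a "dACA" gene encoding the identical protein).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .errors import InsufficientDataError, ParameterError, RecodingInfeasibleError

_VALID = frozenset("ACGT")

# Relative codon usage in E. coli K-12 (approximate fractions per amino acid),
# used only to order synonymous candidates deterministically during recoding.
_ECOLI_USAGE: Dict[str, float] = {
    "TTT": 0.57, "TTC": 0.43, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10,
    "CTC": 0.10, "CTA": 0.04, "CTG": 0.50, "ATT": 0.51, "ATC": 0.42,
    "ATA": 0.07, "ATG": 1.00, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15,
    "GTG": 0.37, "TCT": 0.15, "TCC": 0.15, "TCA": 0.12, "TCG": 0.15,
    "AGT": 0.15, "AGC": 0.28, "CCT": 0.16, "CCC": 0.12, "CCA": 0.19,
    "CCG": 0.53, "ACT": 0.17, "ACC": 0.44, "ACA": 0.13, "ACG": 0.27,
    "GCT": 0.16, "GCC": 0.27, "GCA": 0.21, "GCG": 0.36, "TAT": 0.57,
    "TAC": 0.43, "CAT": 0.57, "CAC": 0.43, "CAA": 0.35, "CAG": 0.65,
    "AAT": 0.45, "AAC": 0.55, "AAA": 0.77, "AAG": 0.23, "GAT": 0.63,
    "GAC": 0.37, "GAA": 0.69, "GAG": 0.31, "TGT": 0.45, "TGC": 0.55,
    "TGG": 1.00, "CGT": 0.38, "CGC": 0.40, "CGA": 0.06, "CGG": 0.10,
    "AGA": 0.04, "AGG": 0.02, "GGT": 0.34, "GGC": 0.40, "GGA": 0.11,
    "GGG": 0.15, "TAA": 0.64, "TAG": 0.07, "TGA": 0.29,
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _synonyms() -> Dict[str, List[str]]:
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(_STANDARD_TABLE.stop_codons)
    table: Dict[str, List[str]] = {}
    for codons in by_aa.values():
        ordered = sorted(codons, key=lambda c: (-_ECOLI_USAGE.get(c, 0.0), c))
        for c in codons:
            table[c] = ordered
    return table


_SYNONYMS = _synonyms()


@dataclass
class CodingSequence:
    """A nucleotide coding sequence with reading-frame bookkeeping."""

    id: str
    nucleotides: str
    frame: int = 0
    strand_note: str = "+"

    def __post_init__(self):
        self.nucleotides = str(self.nucleotides).upper()

    def validate(self, in_frame: bool = False) -> "CodingSequence":
        bad = [i for i, ch in enumerate(self.nucleotides) if ch not in _VALID]
        if bad:
            raise ParameterError(
                "nucleotides",
                f"invalid characters at positions {bad[:20]}"
                + ("..." if len(bad) > 20 else ""))
        if in_frame and (len(self.nucleotides) - self.frame) % 3 != 0:
            raise ParameterError(
                "nucleotides",
                f"length from frame offset {self.frame} is not a multiple of 3")
        return self

    @property
    def coding_region(self) -> str:
        return self.nucleotides[self.frame:]

    @property
    def protein(self) -> str:
        self.validate(in_frame=True)
        return str(Seq(self.coding_region).translate())

    def __len__(self) -> int:
        return len(self.nucleotides)


def read_fasta(path) -> List[CodingSequence]:
    return [CodingSequence(id=rec.id, nucleotides=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Sequence[CodingSequence], path) -> None:
    records = [SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def find_ACA(seq: Union[CodingSequence, str]) -> List[int]:
    """0-based start positions of every (overlapping) ACA occurrence."""
    if isinstance(seq, CodingSequence):
        seq.validate()
        s = seq.nucleotides
    else:
        s = str(seq).upper()
        CodingSequence(id="_", nucleotides=s).validate()
    return [m.start() for m in re.finditer(r"(?=ACA)", s)]


def region_weights(count_E: int, count_F: int) -> float:
    """Cleavage-weight ratio w_F / w_E from per-region ACA-site counts.

    With weights proportional to site counts, the toxin-encoding region of a
    transcript with ``count_F`` sites is ``count_F / count_E`` times more
    likely to be cleaved than the antitoxin-encoding region.
    """
    if count_E <= 0:
        raise ParameterError("count_E", "antitoxin-region site count must be > 0 "
                                        "(weight ratio undefined)")
    if count_F <= 0:
        raise ParameterError("count_F", "toxin-region site count must be > 0")
    return count_F / count_E


def recode_remove_ACA(seq: CodingSequence, max_states: int = 10_000) -> CodingSequence:
    """Synonymously recode ``seq`` so that no ACA remains.

    Depth-first search over synonymous codon swaps: the leftmost unresolved
    ACA is attacked first; for each of the (at most two) codons it touches,
    alternatives are tried in decreasing E. coli usage order; a candidate is
    kept only if it pushes the leftmost ACA strictly rightwards, and the
    search backtracks otherwise, so fixing one site never permanently
    introduces another.  Raises :class:`RecodingInfeasibleError` (reporting
    the stuck positions) if no assignment works within ``max_states``
    expansions.
    """
    seq.validate(in_frame=True)
    prefix = seq.nucleotides[:seq.frame]
    codons = [seq.coding_region[i:i + 3] for i in range(0, len(seq.coding_region), 3)]
    protein = seq.protein

    def leftmost(s: str) -> int:
        i = s.find("ACA")
        return i if i >= 0 else len(s) + 1

    states = 0

    def search(codons: List[str], pos: int) -> Optional[List[str]]:
        nonlocal states
        s = prefix + "".join(codons)
        i = s.find("ACA")
        if i < 0:
            return codons
        c_lo = max((i - seq.frame) // 3, 0)
        c_hi = min((i + 2 - seq.frame) // 3, len(codons) - 1)
        if i + 2 < seq.frame:
            return None   # ACA confined to the immutable prefix
        for ci in range(c_lo, c_hi + 1):
            current = codons[ci]
            for alt in _SYNONYMS.get(current, [current]):
                if alt == current:
                    continue
                states += 1
                if states > max_states:
                    return None
                trial = codons.copy()
                trial[ci] = alt
                if leftmost(prefix + "".join(trial)) <= i:
                    continue
                result = search(trial, i + 1)
                if result is not None:
                    return result
        return None

    result = search(codons, 0)
    if result is None:
        stuck = find_ACA(CodingSequence(id=seq.id, nucleotides=prefix + "".join(codons)))
        raise RecodingInfeasibleError(stuck)
    out = CodingSequence(id=f"{seq.id}_dACA", nucleotides=prefix + "".join(result),
                         frame=seq.frame, strand_note=seq.strand_note)
    assert out.protein == protein
    assert not find_ACA(out)
    return out


def relative_abundance(ct_target_t: float, ct_ref_t: float,
                       ct_target_0: float, ct_ref_0: float,
                       efficiency: float = 2.0) -> float:
    """Fold mRNA remaining at time t by the delta-delta-Ct method.

    efficiency^-[(Ct_target,t - Ct_ref,t) - (Ct_target,0 - Ct_ref,0)],
    i.e. abundance relative to the reference gene, normalized to time zero.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ParameterError("efficiency", f"must lie in (1, 2], got {efficiency!r}")
    ddct = (ct_target_t - ct_ref_t) - (ct_target_0 - ct_ref_0)
    return float(efficiency ** (-ddct))


@dataclass
class DecaySeries:
    """A qRT-PCR decay series: target and reference Ct over >= 5 time points."""

    times: np.ndarray
    ct_target: np.ndarray
    ct_ref: np.ndarray
    efficiency: float = 2.0
    region: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ct_target = np.asarray(self.ct_target, dtype=float)
        self.ct_ref = np.asarray(self.ct_ref, dtype=float)

    def validate(self) -> "DecaySeries":
        if self.times.size != self.ct_target.size or self.times.size != self.ct_ref.size:
            raise ParameterError("times", "times/ct_target/ct_ref sizes differ")
        if self.times.size < 2 or self.times[0] != 0.0:
            raise ParameterError("times", "series must start at time 0")
        if (np.diff(self.times) <= 0).any():
            raise ParameterError("times", "times must be strictly increasing")
        return self

    def abundances(self) -> np.ndarray:
        """Relative abundance (fold remaining) at each time point."""
        self.validate()
        return np.array([
            relative_abundance(self.ct_target[i], self.ct_ref[i],
                               self.ct_target[0], self.ct_ref[0], self.efficiency)
            for i in range(self.times.size)])

    @classmethod
    def from_ct_table(cls, table: pd.DataFrame, target: str, reference: str,
                      efficiency: float = 2.0, replicate=None) -> "DecaySeries":
        """Build from a tidy Ct table (columns time_min, gene, replicate, ct),
        averaging Ct over replicates unless one is selected."""
        df = table
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        pivot = df.pivot_table(index="time_min", columns="gene", values="ct")
        if target not in pivot or reference not in pivot:
            raise ParameterError("table", f"genes {target!r}/{reference!r} not found")
        times = pivot.index.to_numpy(dtype=float)
        return cls(times=times, ct_target=pivot[target].to_numpy(),
                   ct_ref=pivot[reference].to_numpy(), efficiency=efficiency)


@dataclass
class HalfLifeResult:
    t_half: float            # minutes (inf when the series does not decay)
    rate: float              # first-order decay rate lambda (1/min)
    stderr_rate: float       # regression SE of lambda
    stderr_t_half: float     # delta-method SE of t_half
    non_decaying: bool


def half_life(series: DecaySeries) -> HalfLifeResult:
    """First-order mRNA half-life from a decay series.

    Least-squares slope of ln(relative abundance) versus time gives the
    decay rate lambda; t1/2 = ln 2 / lambda.  A non-decaying series
    (lambda <= 0) is flagged and reported with infinite half-life.
    """
    ab = series.abundances()
    post = series.times > 0
    if int(post.sum()) < 3 or (ab[post] <= 0).any():
        raise InsufficientDataError(
            "half-life needs >= 3 post-zero points with positive abundance")
    fit = stats.linregress(series.times, np.log(ab))
    lam = -fit.slope
    se = float(fit.stderr)
    if lam <= 0:
        return HalfLifeResult(math.inf, float(lam), se, math.inf, True)
    t12 = math.log(2) / lam
    return HalfLifeResult(float(t12), float(lam), se,
                          float(math.log(2) / lam ** 2 * se), False)


def packaged_cds(name: str) -> CodingSequence:
    """Load one of the packaged coding-sequence fixtures.

    ``"mazE"``/``"mazF"`` map to synthetic stand-in CDSs carrying the ACA
    site counts of the respective E. coli cistrons (2 and 9).
    """
    fname = {"mazE": "mazE_like_synthetic.fasta",
             "mazF": "mazF_like_synthetic.fasta"}.get(name)
    if fname is None:
        raise ParameterError("name", f"unknown fixture {name!r}")
    path = Path(__file__).parent / "data" / fname
    return read_fasta(path)[0]
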