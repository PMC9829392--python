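"""LNA-aware melting temperature, hybridization temperature, and hairpin
screening for designed oligos.

Duplex Tm is a unified nearest-neighbor computation (SantaLucia 1998
parameter set as shipped with Biopython) with an entropy-based monovalent
salt correction.  LNA substitutions are handled as a configurable per-base
Tm increment (default +2 degC per locked base) rather than LNA-specific
nearest-neighbor tables: the increment is the well-known first-order effect
of a locked ribose, it is transparent, and it is swappable through
:class:`ThermoParams`.  The assay contract that everything downstream relies
on is simpler still: the hybridization temperature is always set exactly
10 degC below the predicted Tm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping

from Bio.SeqUtils import MeltingTemp as mt

from .seq_core import Alphabet, NucSeq

__all__ = [
    "ThermoParams",
    "TmReport",
    "melting_temperature",
    "recommend_hybridization_temperature",
    "tm_report",
    "hairpin_stem",
    "HYBRIDIZATION_OFFSET_C",
]

# The hybridization temperature is a fixed offset below the predicted Tm.
HYBRIDIZATION_OFFSET_C = 10.0

_DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def _nn_key_present(table: Mapping[str, tuple], dinuc: str) -> bool:
    comp = dinuc.translate(str.maketrans("ACGT", "TGCA"))
    fwd = f"{dinuc}/{comp}"
    rev = f"{comp[::-1]}/{dinuc[::-1]}"
    return fwd in table or rev in table


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor table plus solution conditions.

    nn_table     -- dinucleotide (dH kcal/mol, dS cal/mol/K) entries; every
                    one of the 16 dinucleotide stacks must be resolvable
                    directly or via its reverse-complement key.
    na_molar     -- monovalent cation concentration.  Default 0.75 M, the
                    NaCl contribution of the 5x SSC hybridization buffer.
    oligo_molar  -- probe and target strand concentration.  Default 0.1 uM,
                    a typical detection-oligo working concentration.
    lna_delta_tm -- Tm increment per LNA-modified base (degC, >= 0).
    """

    nn_table: Mapping[str, tuple] = field(default_factory=lambda: mt.DNA_NN3)
    na_molar: float = 0.75
    oligo_molar: float = 1e-7
    lna_delta_tm: float = 2.0

    def __post_init__(self) -> None:
        missing = [d for d in _DINUCLEOTIDES if not _nn_key_present(self.nn_table, d)]
        if missing:
            raise ValueError(f"nearest-neighbor table missing stacks: {missing}")
        if self.na_molar <= 0:
            raise ValueError("salt concentration must be positive")
        if self.oligo_molar <= 0:
            raise ValueError("oligo concentration must be positive")
        if self.lna_delta_tm < 0:
            raise ValueError("lna_delta_tm must be >= 0")


DEFAULT_THERMO = ThermoParams()


def melting_temperature(
    duplex_region: NucSeq,
    lna_positions: AbstractSet[int] = frozenset(),
    params: ThermoParams | None = None,
) -> float:
    """Predicted Tm (degC) of a perfectly matched duplex over
    `duplex_region`, including the additive LNA increment.

    `lna_positions` are 1-based indices into the duplex region.
    """
    params = params or DEFAULT_THERMO
    s = duplex_region.as_dna()
    n = len(s)
    if n < 8:
        raise ValueError(f"duplex region of {n} nt is too short (need >= 8)")
    bad = [p for p in lna_positions if not 1 <= p <= n]
    if bad:
        raise ValueError(f"LNA positions {sorted(bad)} outside 1..{n}")
    tm = mt.Tm_NN(
        s.residues,
        nn_table=dict(params.nn_table),
        Na=params.na_molar * 1000.0,  # mM
        dnac1=params.oligo_molar * 1e9,  # nM
        dnac2=params.oligo_molar * 1e9,
        saltcorr=5,
    )
    return float(tm + params.lna_delta_tm * len(lna_positions))


def recommend_hybridization_temperature(tm: float) -> float:
    """Hybridization temperature: exactly Tm - 10 degC."""
    if not math.isfinite(tm):
        raise ValueError(f"non-finite Tm: {tm}")
    return tm - HYBRIDIZATION_OFFSET_C


@dataclass(frozen=True)
class TmReport:
    tm: float
    hybridization_temperature: float
    method: str

    def __post_init__(self) -> None:
        if abs(self.hybridization_temperature - (self.tm - HYBRIDIZATION_OFFSET_C)) > 1e-9:
            raise ValueError(
                "hybridization_temperature must equal tm - "
                f"{HYBRIDIZATION_OFFSET_C} exactly"
            )


def tm_report(
    duplex_region: NucSeq,
    lna_positions: AbstractSet[int] = frozenset(),
    params: ThermoParams | None = None,
) -> TmReport:
    tm = melting_temperature(duplex_region, lna_positions, params)
    return TmReport(
        tm=tm,
        hybridization_temperature=recommend_hybridization_temperature(tm),
        method="nearest-neighbor + per-base LNA increment",
    )


_PAIRS = {
    Alphabet.DNA: {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")},
    Alphabet.RNA: {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")},
}


def hairpin_stem(s: NucSeq, min_loop: int = 3) -> int:
    """Longest self-complementary stem (bases) foldable with a loop of at
    least `min_loop` unpaired bases; 0 if the sequence cannot fold.

    Only Watson-Crick pairs count.  O(n^2) dynamic program: R[i][j] is the
    length of the antiparallel complementary run pairing outward positions
    (i, j) inward; a stem of length L at (i, j) is admissible when
    L <= (j - i + 1 - min_loop) // 2.
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    r = s.residues
    n = len(r)
    pairs = _PAIRS[s.alphabet]
    best = 0
    run_next = [0] * (n + 1)  # run lengths for row i+1
    for i in range(n - 2, -1, -1):
        run_here = [0] * (n + 1)
        for j in range(n - 1, i, -1):
            if (r[i], r[j]) in pairs:
                run_here[j] = run_next[j - 1] + 1
                cap = (j - i + 1 - min_loop) // 2
                stem = min(run_here[j], cap)
                if stem > best:
                    best = stem
        run_next = run_here
    return best
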