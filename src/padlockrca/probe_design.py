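"""Design and validation of the complete in situ detection probe set.

A miRNA assay is a chain of four oligos whose pairwise complementarities
must close into a single detectable circle:

* the miRNA-LNA probe -- a DNA oligo of (miRNA length + 30) bases whose 5'
  region is the perfect antiparallel complement of the target miRNA, with
  LNA-locked bases at positions 2, 4, 6, 8 and 10, and whose 3' 30 bases
  are a transcriptome-unique linker;
* the padlock probe -- an 80-base 5'-phosphorylated oligo laid out as
  15-base 5' arm + 20-base detection-oligo binding site + 30-base backbone
  + 15-base 3' arm; the two arms anneal head-to-tail on the linker so that
  a ligase can seal the nick and circularize the probe;
* rolling-circle amplification then concatemerizes the complement of the
  circle, and
* the detection oligo -- the 20-mer equal to the padlock's detection site
  (circle sense), hence complementary to the repeated sites of the RCA
  product.

The mRNA assay replaces the miRNA-LNA probe by an LNA reverse-transcription
primer plus a padlock that targets a transcriptome-unique 30-base window of
the resulting cDNA.

"Perfect match" of probe to target is implemented throughout as perfect
antiparallel complementarity: that is what hybridization geometry requires,
and it is what maps target mismatches at positions 11-19 onto the probe's
5' LNA-modified region, where a single mismatch abolishes the signal.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import AbstractSet, Iterable, Sequence

import numpy as np

from . import __version__ as _version
from .seq_core import (
    Alphabet,
    KmerIndex,
    MiRNARecord,
    NucSeq,
    count_index_hits,
    gc_content,
    reverse_complement,
)
from .thermo import ThermoParams, hairpin_stem, melting_temperature, recommend_hybridization_temperature

__all__ = [
    "DesignError",
    "DesignConstraints",
    "MiRNALNAProbe",
    "PadlockProbe",
    "DetectionOligo",
    "MRNAAssay",
    "MRNAAssayConfig",
    "SignalClass",
    "MismatchCall",
    "StepResult",
    "ValidationReport",
    "LNA_POSITIONS",
    "ARM_LEN",
    "DETECTION_LEN",
    "BACKBONE_LEN",
    "PADLOCK_LEN",
    "LINKER_LEN",
    "design_mirna_lna_probe",
    "generate_unique_oligo",
    "design_padlock",
    "design_mrna_assay",
    "simulate_rca_product",
    "validate_probe_set",
    "predict_mismatch_signal",
    "lna_plus_notation",
    "write_order_sheet",
]

# Fixed architecture of the probe set.
LNA_POSITIONS = frozenset({2, 4, 6, 8, 10})  # 1-based from the 5' end
LINKER_LEN = 30
ARM_LEN = 15
DETECTION_LEN = 20
BACKBONE_LEN = 30
PADLOCK_LEN = 2 * ARM_LEN + DETECTION_LEN + BACKBONE_LEN  # 80


class DesignError(RuntimeError):
    """Raised when a design operation cannot satisfy its constraints."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MiRNALNAProbe:
    """The miRNA detection probe: complementarity region + unique linker."""

    id: str
    full_sequence: NucSeq
    target_length: int
    lna_positions: frozenset[int] = LNA_POSITIONS

    def __post_init__(self) -> None:
        if self.full_sequence.alphabet is not Alphabet.DNA:
            raise DesignError("probe must be a DNA oligo")
        if len(self.full_sequence) != self.target_length + LINKER_LEN:
            raise DesignError(
                f"probe length {len(self.full_sequence)} != target length "
                f"{self.target_length} + {LINKER_LEN}"
            )
        if not all(1 <= p <= self.target_length for p in self.lna_positions):
            raise DesignError("LNA positions must fall inside the hybridization region")

    @property
    def hybridization_region(self) -> NucSeq:
        return NucSeq(self.full_sequence.residues[: self.target_length])

    @property
    def linker(self) -> NucSeq:
        return NucSeq(self.full_sequence.residues[self.target_length :])


@dataclass(frozen=True)
class PadlockProbe:
    """80-base circularizable probe: arm5 + detection site + backbone + arm3."""

    id: str
    full_sequence: NucSeq
    phosphorylated: bool = True

    def __post_init__(self) -> None:
        if self.full_sequence.alphabet is not Alphabet.DNA:
            raise DesignError("padlock must be a DNA oligo")
        if len(self.full_sequence) != PADLOCK_LEN:
            raise DesignError(
                f"padlock length {len(self.full_sequence)} != {PADLOCK_LEN}"
            )
        if not self.phosphorylated:
            raise DesignError("padlock must be 5'-phosphorylated to ligate")

    @property
    def arm5(self) -> NucSeq:
        return NucSeq(self.full_sequence.residues[:ARM_LEN])

    @property
    def detection_site(self) -> NucSeq:
        return NucSeq(self.full_sequence.residues[ARM_LEN : ARM_LEN + DETECTION_LEN])

    @property
    def backbone(self) -> NucSeq:
        a = ARM_LEN + DETECTION_LEN
        return NucSeq(self.full_sequence.residues[a : a + BACKBONE_LEN])

    @property
    def arm3(self) -> NucSeq:
        return NucSeq(self.full_sequence.residues[-ARM_LEN:])


@dataclass(frozen=True)
class DetectionOligo:
    """Fluorophore-tagged 20-mer read out from the RCA product.

    Its sequence equals the padlock detection site (circle sense), so it is
    complementary to the RCA product, which is the complement of the circle.
    """

    id: str
    sequence: NucSeq
    fluorophore: str = "Cy3"

    def __post_init__(self) -> None:
        if len(self.sequence) != DETECTION_LEN:
            raise DesignError(
                f"detection oligo must be {DETECTION_LEN} nt, got {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MRNAAssay:
    """LNA reverse-transcription primer plus a cDNA-targeted padlock.

    ``cdna_window`` and ``primer_site`` are 1-based inclusive transcript
    coordinates; the window lies 5' of the primer site so reverse
    transcription (which runs 3'->5' along the transcript) can copy it.
    """

    transcript_id: str
    lna_primer: NucSeq
    lna_positions: frozenset[int]
    primer_site: tuple[int, int]
    padlock: PadlockProbe
    cdna_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.cdna_window[1] >= self.primer_site[0]:
            raise DesignError(
                "cDNA window must lie 5' of the primer site on the transcript"
            )


class SignalClass(str, Enum):
    REFERENCE = "REFERENCE"
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    NONE = "NONE"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class MismatchCall:
    position: int
    signal_class: SignalClass
    score: float | None


# ---------------------------------------------------------------------------
# constrained random oligo generation (linkers, backbones, detection sites)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConstraints:
    """Thresholds for linker/backbone generation.

    GC bounds come straight from the backbone design guidelines (50-60%).
    Base balance requires each base count within length/4 +- length/20
    (for a 30-mer: 6..9 of each base) and no homopolymer run longer than
    ``run_max`` -- an operational reading of "similar and evenly
    distributed".  ``stem_max`` is the longest tolerated self-complementary
    stem (stems of 4+ are rejected); ``max_index_hits`` is the number of
    transcriptome k-mer collisions tolerated (default none).
    """

    gc_min: float = 0.50
    gc_max: float = 0.60
    balance_halfband: float = 0.05  # fraction of length; +-length/20
    run_max: int = 3
    stem_max: int = 3
    min_loop: int = 3
    max_index_hits: int = 0
    max_attempts: int = 20000

    def base_count_band(self, length: int) -> tuple[int, int]:
        half = self.balance_halfband * length
        return (
            int(math.floor(length / 4 - half)),
            int(math.ceil(length / 4 + half)),
        )


DEFAULT_CONSTRAINTS = DesignConstraints()


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _compositions(length: int, c: DesignConstraints) -> list[tuple[int, int, int, int]]:
    lo, hi = c.base_count_band(length)
    lo = max(lo, 0)
    gc_lo = math.ceil(c.gc_min * length - 1e-9)
    gc_hi = math.floor(c.gc_max * length + 1e-9)
    out = []
    for nc in range(lo, hi + 1):
        for ng in range(lo, hi + 1):
            if not gc_lo <= nc + ng <= gc_hi:
                continue
            for na in range(lo, hi + 1):
                nt = length - nc - ng - na
                if lo <= nt <= hi:
                    out.append((na, nc, ng, nt))
    return out


def generate_unique_oligo(
    length: int,
    index: KmerIndex,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
) -> NucSeq:
    """Draw a random DNA oligo satisfying all design constraints.

    Base composition (GC band + balance) is sampled constructively, then
    homopolymer runs, hairpin stems and k-mer index collisions are checked
    by rejection.  Deterministic for a fixed seed.  Raises
    :class:`DesignError` with per-constraint failure counts if
    ``max_attempts`` draws never satisfy the full set.
    """
    c = constraints or DEFAULT_CONSTRAINTS
    comps = _compositions(length, c)
    if not comps:
        raise DesignError(
            f"no base composition of length {length} satisfies the GC and "
            "balance bands"
        )
    rng = np.random.default_rng(seed)
    fails: Counter[str] = Counter()
    screen_index = len(index) > 0 and length >= index.k
    for _ in range(c.max_attempts):
        na, nc, ng, nt = comps[rng.integers(len(comps))]
        arr = np.array(list("A" * na + "C" * nc + "G" * ng + "T" * nt))
        rng.shuffle(arr)
        s = "".join(arr)
        if _max_run(s) > c.run_max:
            fails["homopolymer_run"] += 1
            continue
        seq = NucSeq(s)
        if hairpin_stem(seq, c.min_loop) > c.stem_max:
            fails["hairpin_stem"] += 1
            continue
        if screen_index and count_index_hits(seq, index) > c.max_index_hits:
            fails["index_hits"] += 1
            continue
        return seq
    tightest = fails.most_common(1)[0][0] if fails else "composition"
    raise DesignError(
        f"no {length}-mer satisfying constraints after {c.max_attempts} "
        f"attempts; tightest constraint: {tightest}; failure counts: "
        f"{dict(fails)}"
    )


# ---------------------------------------------------------------------------
# design operations
# ---------------------------------------------------------------------------


def design_mirna_lna_probe(
    mirna: MiRNARecord,
    index: KmerIndex,
    seed: int = 0,
    constraints: DesignConstraints | None = None,
    probe_id: str | None = None,
) -> MiRNALNAProbe:
    """Build the miRNA-LNA probe: reverse complement of the miRNA (DNA
    strand) followed by a transcriptome-unique 30-base linker."""
    hyb = reverse_complement(mirna.sequence, to_dna=True)
    linker = generate_unique_oligo(LINKER_LEN, index, constraints, seed)
    full = NucSeq(hyb.residues + linker.residues)
    return MiRNALNAProbe(
        id=probe_id or f"{mirna.id}_LNA_probe",
        full_sequence=full,
        target_length=len(mirna.sequence),
    )


def design_padlock(
    template_30mer: NucSeq,
    detection_site: NucSeq,
    backbone: NucSeq,
    padlock_id: str = "padlock",
) -> PadlockProbe:
    """Assemble the 80-base padlock for a given 30-base template.

    Reading the circularized padlock across the ligation junction (3' arm
    then 5' arm) must give the reverse complement of the template, placing
    the nick exactly between template positions 15 and 16 with zero gap:
    the 3' arm anneals to the template's 3' half, the 5'-phosphorylated arm
    to its 5' half, head-to-tail.
    """
    template_30mer = template_30mer.as_dna()
    if len(template_30mer) != 2 * ARM_LEN:
        raise DesignError(f"template must be {2 * ARM_LEN} nt")
    if len(detection_site) != DETECTION_LEN:
        raise DesignError(f"detection site must be {DETECTION_LEN} nt")
    if len(backbone) != BACKBONE_LEN:
        raise DesignError(f"backbone must be {BACKBONE_LEN} nt")
    junction = reverse_complement(template_30mer).residues
    arm3, arm5 = junction[:ARM_LEN], junction[ARM_LEN:]
    full = NucSeq(
        arm5 + detection_site.as_dna().residues + backbone.as_dna().residues + arm3
    )
    return PadlockProbe(id=padlock_id, full_sequence=full)


def simulate_rca_product(padlock: PadlockProbe, n_repeats: int = 3) -> NucSeq:
    """Phi29 output for the circularized padlock: the tandem reverse
    complement of the circle.

    The product is reported starting from the ligation junction; any
    rotation is equivalent, and consumers should search the doubled repeat
    unit to be rotation-safe.
    """
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    unit = reverse_complement(padlock.full_sequence).residues
    return NucSeq(unit * n_repeats)


@dataclass(frozen=True)
class StepResult:
    step: int
    name: str
    passed: bool
    detail: str = ""
    positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    steps: tuple[StepResult, ...]

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.steps)

    def step(self, number: int) -> StepResult:
        for s in self.steps:
            if s.step == number:
                return s
        raise KeyError(number)


def _mismatch_positions(observed: str, expected: str) -> tuple[int, ...]:
    if len(observed) != len(expected):
        return tuple(range(1, max(len(observed), len(expected)) + 1))
    return tuple(i + 1 for i, (a, b) in enumerate(zip(observed, expected)) if a != b)


def validate_probe_set(
    mirna: MiRNARecord,
    probe: MiRNALNAProbe,
    padlock: PadlockProbe,
    det: DetectionOligo,
) -> ValidationReport:
    """Walk the five-step detection chemistry and report each check.

    I   miRNA |- probe: the hybridization region is the full antiparallel
        complement of the miRNA.
    II  padlock arms anneal to the linker with contiguous full coverage
        (arm5 on linker bases 1-15, arm3 on 16-30).
    III the nick is ligatable: zero gap, and the two junction-flanking base
        pairs (linker positions 15 and 16) are perfect.
    IV  the simulated RCA product is the tandem reverse complement of the
        circle.
    V   the detection oligo reads out the product: its sequence occurs in
        the circle sense, hence its complement in every repeat.
    Failures are report entries with 1-based offending positions, never
    exceptions.
    """
    steps: list[StepResult] = []

    expected_hyb = reverse_complement(mirna.sequence, to_dna=True).residues
    obs_hyb = probe.hybridization_region.residues
    mism = _mismatch_positions(obs_hyb, expected_hyb)
    steps.append(
        StepResult(1, "miRNA-probe hybridization", not mism,
                   "positions index the hybridization region", mism)
    )

    linker = probe.linker.residues
    foot5 = reverse_complement(padlock.arm5).residues  # where arm5 anneals
    foot3 = reverse_complement(padlock.arm3).residues
    mism5 = _mismatch_positions(linker[:ARM_LEN], foot5)
    mism3 = tuple(p + ARM_LEN for p in _mismatch_positions(linker[ARM_LEN:], foot3))
    steps.append(
        StepResult(2, "padlock arms anneal to linker", not (mism5 or mism3),
                   "positions index the linker", mism5 + mism3)
    )

    # nick between linker positions 15 and 16: arm5's 5'-phosphorylated end
    # pairs linker base 15, arm3's 3'-OH end pairs linker base 16
    comp = str.maketrans("ACGT", "TGCA")
    junction_bad = []
    if padlock.arm5.residues[0].translate(comp) != linker[ARM_LEN - 1]:
        junction_bad.append(ARM_LEN)
    if padlock.arm3.residues[-1].translate(comp) != linker[ARM_LEN]:
        junction_bad.append(ARM_LEN + 1)
    steps.append(
        StepResult(3, "nick ligatable (zero gap)", not junction_bad,
                   "junction-flanking linker positions", tuple(junction_bad))
    )

    product = simulate_rca_product(padlock, n_repeats=3).residues
    circle = padlock.full_sequence.residues
    unit_ok = all(
        reverse_complement(
            NucSeq(product[i * PADLOCK_LEN : (i + 1) * PADLOCK_LEN])
        ).residues == circle
        for i in range(3)
    )
    steps.append(
        StepResult(4, "RCA product is tandem complement of circle", unit_ok)
    )

    det_in_circle = det.sequence.as_dna().residues in (circle + circle)
    det_rc = reverse_complement(det.sequence.as_dna()).residues
    det_reads_product = det_rc in (product[:PADLOCK_LEN] + product[:PADLOCK_LEN])
    steps.append(
        StepResult(5, "detection oligo hybridizes to RCA product",
                   det_in_circle and det_reads_product)
    )

    return ValidationReport(steps=tuple(steps))


def predict_mismatch_signal(position: int, length: int = 20) -> MismatchCall:
    """Expected detection signal for a single mismatch at a 1-based target
    position (0 = perfectly matched reference).

    Calibrated on a 20-nt target: signal decreases gradually as the
    mismatch moves from position 2 to 10 and is abolished for positions
    11 to 19, which pair with the probe's 5' LNA-modified region (target
    position p pairs probe position length+1-p).  The terminal positions
    1 and `length` have no empirical calibration and are reported
    UNTESTED.  Scores are an ordinal scale: only their ordering and the
    zero region carry meaning.
    """
    if not 0 <= position <= length:
        raise ValueError(f"position {position} outside 0..{length}")
    if position == 0:
        return MismatchCall(0, SignalClass.REFERENCE, 1.0)
    if position in (1, length):
        return MismatchCall(position, SignalClass.UNTESTED, None)
    if 2 <= position <= 10:
        score = round(0.9 - 0.1 * (position - 2), 10)
        if score >= 0.7:
            cls = SignalClass.HIGH
        elif score >= 0.3:
            cls = SignalClass.MODERATE
        else:
            cls = SignalClass.LOW
        return MismatchCall(position, cls, score)
    return MismatchCall(position, SignalClass.NONE, 0.0)


@dataclass(frozen=True)
class MRNAAssayConfig:
    """Knobs for the mRNA assay: primer geometry and cDNA window bounds."""

    primer_length: int = 25
    spacer: int = 10  # unpaired transcript bases between window and primer
    primer_gc_min: float = 0.30
    primer_gc_max: float = 0.70
    window_gc_min: float = 0.40
    window_gc_max: float = 0.60
    max_window_hits: int = 0
    lna_positions: frozenset[int] = LNA_POSITIONS


def design_mrna_assay(
    transcript: NucSeq,
    index: KmerIndex,
    config: MRNAAssayConfig | None = None,
    seed: int = 0,
    transcript_id: str = "transcript",
    constraints: DesignConstraints | None = None,
) -> MRNAAssay:
    """Design the LNA primer + cDNA-targeted padlock for one transcript.

    `index` must be the transcriptome index built *without* the target
    transcript (leave-one-out), so window uniqueness means "unique among
    everything else".  The primer is placed as close to the transcript 3'
    end as its GC bound allows; the 30-base padlock target window is the
    3'-most admissible window 5' of the primer (GC-bounded, zero canonical
    k-mer hits).  The padlock is built against the cDNA sense of that
    window, so its two arms jointly read the transcript substring exactly.
    """
    cfg = config or MRNAAssayConfig()
    t = transcript.as_dna().residues
    n = len(t)
    min_len = cfg.primer_length + 2 * ARM_LEN + cfg.spacer
    if n < min_len:
        raise DesignError(
            f"transcript of {n} nt shorter than minimum {min_len} "
            f"(primer {cfg.primer_length} + window {2 * ARM_LEN} + spacer "
            f"{cfg.spacer})"
        )
    fails: Counter[str] = Counter()
    scanned = 0
    found: tuple[int, int] | None = None
    for p in range(n - cfg.primer_length, 2 * ARM_LEN + cfg.spacer - 1, -1):
        site = NucSeq(t[p : p + cfg.primer_length])
        if not cfg.primer_gc_min <= gc_content(site) <= cfg.primer_gc_max:
            fails["primer_gc"] += 1
            continue
        for w in range(p - cfg.spacer - 2 * ARM_LEN, -1, -1):
            scanned += 1
            win = NucSeq(t[w : w + 2 * ARM_LEN])
            if not cfg.window_gc_min <= gc_content(win) <= cfg.window_gc_max:
                fails["window_gc"] += 1
                continue
            if len(index) and count_index_hits(win, index) > cfg.max_window_hits:
                fails["window_index_hits"] += 1
                continue
            found = (p, w)
            break
        if found:
            break
    if not found:
        raise DesignError(
            f"no admissible primer/window placement on {transcript_id!r}; "
            f"scanned {scanned} windows; failure counts: {dict(fails)}"
        )
    p, w = found
    window = NucSeq(t[w : w + 2 * ARM_LEN])
    template = reverse_complement(window)  # the cDNA rendering of the window
    rng = np.random.default_rng(seed)
    det_seed, bb_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
    det_site = generate_unique_oligo(DETECTION_LEN, index, constraints, det_seed)
    backbone = generate_unique_oligo(BACKBONE_LEN, index, constraints, bb_seed)
    padlock = design_padlock(
        template, det_site, backbone, padlock_id=f"{transcript_id}_padlock"
    )
    primer = reverse_complement(NucSeq(t[p : p + cfg.primer_length]))
    return MRNAAssay(
        transcript_id=transcript_id,
        lna_primer=primer,
        lna_positions=cfg.lna_positions,
        primer_site=(p + 1, p + cfg.primer_length),
        padlock=padlock,
        cdna_window=(w + 1, w + 2 * ARM_LEN),
    )


# ---------------------------------------------------------------------------
# order sheet
# ---------------------------------------------------------------------------


def lna_plus_notation(seq: NucSeq, lna_positions: AbstractSet[int]) -> str:
    """Vendor rendering with '+' preceding each LNA base, e.g. G+TG+C..."""
    return "".join(
        ("+" if (i + 1) in lna_positions else "") + b
        for i, b in enumerate(seq.residues)
    )


@dataclass(frozen=True)
class OrderSheetEntry:
    oligo_id: str
    oligo_type: str  # mirna_lna_probe | mrna_lna_primer | padlock | detection
    sequence: NucSeq
    lna_positions: frozenset[int] = frozenset()
    phosphorylated: bool = False


def order_sheet_entries(
    probe: MiRNALNAProbe | None = None,
    padlock: PadlockProbe | None = None,
    det: DetectionOligo | None = None,
    mrna_assay: MRNAAssay | None = None,
) -> list[OrderSheetEntry]:
    entries: list[OrderSheetEntry] = []
    if probe is not None:
        entries.append(
            OrderSheetEntry(probe.id, "mirna_lna_probe", probe.full_sequence,
                            probe.lna_positions)
        )
    if padlock is not None:
        entries.append(
            OrderSheetEntry(padlock.id, "padlock", padlock.full_sequence,
                            phosphorylated=True)
        )
    if det is not None:
        entries.append(OrderSheetEntry(det.id, "detection", det.sequence))
    if mrna_assay is not None:
        entries.append(
            OrderSheetEntry(f"{mrna_assay.transcript_id}_LNA_primer",
                            "mrna_lna_primer", mrna_assay.lna_primer,
                            mrna_assay.lna_positions)
        )
        entries.append(
            OrderSheetEntry(mrna_assay.padlock.id, "padlock",
                            mrna_assay.padlock.full_sequence,
                            phosphorylated=True)
        )
        entries.append(
            OrderSheetEntry(f"{mrna_assay.transcript_id}_detection",
                            "detection", mrna_assay.padlock.detection_site)
        )
    return entries


def write_order_sheet(
    entries: Sequence[OrderSheetEntry],
    path: str | Path,
    index: KmerIndex | None = None,
    thermo_params: ThermoParams | None = None,
) -> None:
    """Write the tab-delimited order sheet (UTF-8, commented header).

    Tm is computed over the full oligo; for LNA oligos it includes the
    per-base increment.  index_hits is blank when no index is supplied or
    the oligo is shorter than k.
    """
    rows = []
    for e in entries:
        tm = melting_temperature(e.sequence, e.lna_positions, thermo_params)
        hits = ""
        if index is not None and len(e.sequence) >= index.k:
            hits = str(count_index_hits(e.sequence, index))
        rows.append(
            "\t".join(
                [
                    e.oligo_id,
                    e.oligo_type,
                    e.sequence.residues,
                    ",".join(str(p) for p in sorted(e.lna_positions)),
                    lna_plus_notation(e.sequence, e.lna_positions),
                    "yes" if e.phosphorylated else "no",
                    f"{tm:.2f}",
                    f"{recommend_hybridization_temperature(tm):.2f}",
                    f"{gc_content(e.sequence):.4f}",
                    str(hairpin_stem(e.sequence)),
                    hits,
                ]
            )
        )
    header = "\t".join(
        ["oligo_id", "type", "sequence", "lna_positions", "lna_sequence",
         "phosphorylated", "tm_c", "hyb_temp_c", "gc", "hairpin_stem",
         "index_hits"]
    )
    params = thermo_params or ThermoParams()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# padlockrca v{_version} order sheet; sequences 5'->3' DNA; "
            "lna_positions 1-based\n"
            f"# thermo: Na={params.na_molar} M, oligo={params.oligo_molar} M, "
            f"lna_delta_tm={params.lna_delta_tm} C/base\n"
        )
        fh.write(header + "\n")
        fh.write("\n".join(rows) + "\n")
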