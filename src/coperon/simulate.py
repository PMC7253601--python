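"""Synthetic sensorgrams and promoter panels with known ground truth.

Two generators make the whole pipeline testable end to end without external
data:

* :func:`simulate_sensorgram` / :func:`simulate_set` produce Octet-style BLI
  traces under the 1:1 Langmuir model, following the standard protocol phases
  (primary baseline 60 s, loading 150 s, secondary baseline 180 s,
  association 180 s, dissociation 270 s) with Gaussian noise, per-boundary
  step offsets, and optional linear drift.

* :func:`generate_promoter` / :func:`generate_panel` build 100-base upstream
  regions carrying 0, 1 or 2 operator instances drawn from a degenerate
  consensus, on either strand, separated by gaps sampled from a discrete
  triangular distribution on 24-39 bases peaked at 26.  Backgrounds are
  rejection-sampled so a both-strand scan recovers exactly the planted sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    InvalidInputError,
    KineticParams,
    Sensorgram,
    SensorgramSet,
)
from .operators import (
    DegeneratePattern,
    OperatorHit,
    PRESETS,
    compile_pattern,
    reverse_complement,
    scan,
)

__all__ = [
    "DEFAULT_CONCS_M",
    "PhaseSchedule",
    "NoiseModel",
    "PromoterRecord",
    "PlantedOperator",
    "KineticParams",
    "SensorgramSet",
    "simulate_sensorgram",
    "simulate_set",
    "sample_from_pattern",
    "triangular_gap_sampler",
    "generate_promoter",
    "generate_panel",
]

#: Default two-fold protein concentration series, 1000 -> 31.3 nM, in molar.
DEFAULT_CONCS_M: tuple[float, ...] = tuple(
    c * 1e-9 for c in (1000.0, 500.0, 250.0, 125.0, 62.5, 31.3)
)


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the five Octet protocol phases plus sampling interval."""

    primary_baseline: float = 60.0
    loading: float = 150.0
    secondary_baseline: float = 180.0
    association: float = 180.0
    dissociation: float = 270.0
    dt: float = 0.2

    def __post_init__(self) -> None:
        for name in ("primary_baseline", "loading", "secondary_baseline",
                     "association", "dissociation", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    @property
    def durations(self) -> tuple[float, ...]:
        return (self.primary_baseline, self.loading, self.secondary_baseline,
                self.association, self.dissociation)

    @property
    def boundaries(self) -> np.ndarray:
        """Strictly increasing phase end times."""
        return np.cumsum(self.durations)

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time, phase index per sample, phase start time per sample)."""
        bounds = self.boundaries
        t = np.arange(0.0, bounds[-1], self.dt)
        idx = np.searchsorted(bounds, t, side="right")
        starts = np.concatenate([[0.0], bounds[:-1]])[idx]
        return t, idx, starts


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: white Gaussian, per-boundary step offsets, drift.

    Units are response units (and response units/s for drift); the defaults
    are 1% and 2% of the default R_max = 1.0.  All-zero means noiseless.
    """

    gaussian_sd: float = 0.01
    step_offset_sd: float = 0.02
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gaussian_sd, self.step_offset_sd) < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


_PHASE_NAMES = (
    "primary_baseline",
    "loading",
    "secondary_baseline",
    "association",
    "dissociation",
)


def simulate_sensorgram(
    params: KineticParams,
    conc: float,
    schedule: PhaseSchedule | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sensor_id: str | None = None,
    load_level: float = 1.0,
) -> Sensorgram:
    """Simulate one biosensor trace under the 1:1 model.

    The association mean follows R(t) = R_eq (1 - e^(-k_obs t)) with
    k_obs = k_a C + k_d and R_eq = R_max C / (C + K_d); dissociation decays
    from the association end at rate k_d.  Baselines are flat; the loading
    phase is a saturating ramp to ``load_level`` (its kinetics never enter
    any fit).  ``conc = 0`` yields a reference sensor with zero binding
    signal.
    """
    if not np.isfinite(conc) or conc < 0:
        raise InvalidInputError("concentration must be finite and >= 0")
    schedule = schedule or PhaseSchedule()
    noise = noise if noise is not None else NoiseModel()

    t, idx, starts = schedule.grid()
    tl = t - starts  # time within phase
    y = np.zeros_like(t)

    load = idx == 1
    y[load] = load_level * (1.0 - np.exp(-5.0 * tl[load] / schedule.loading))
    y[idx == 2] = load_level

    kobs = params.k_a * conc + params.k_d
    req = params.R_max * conc / (conc + params.K_d) if conc > 0 else 0.0
    assoc = idx == 3
    y[assoc] = load_level + req * (1.0 - np.exp(-kobs * tl[assoc]))
    r_end = req * (1.0 - np.exp(-kobs * schedule.association))
    diss = idx == 4
    y[diss] = load_level + r_end * np.exp(-params.k_d * tl[diss])

    rng = np.random.default_rng(seed)
    if noise.step_offset_sd > 0:
        offsets = np.cumsum(rng.normal(0.0, noise.step_offset_sd, 4))
        y += np.concatenate([[0.0], offsets])[idx]
    if noise.gaussian_sd > 0:
        y += rng.normal(0.0, noise.gaussian_sd, y.size)
    if noise.drift_rate != 0.0:
        y += noise.drift_rate * t

    return Sensorgram(
        time=t,
        response=y,
        phase=np.array(_PHASE_NAMES, dtype=object)[idx],
        analyte_conc=float(conc),
        sensor_id=sensor_id or f"sensor_{conc * 1e9:g}nM",
        is_reference=conc == 0,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % 2**31 for s in state]


def simulate_set(
    params: KineticParams,
    concs: tuple[float, ...] = DEFAULT_CONCS_M,
    schedule: PhaseSchedule | None = None,
    noise: NoiseModel | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> SensorgramSet:
    """One sensorgram per (concentration, replicate) plus a zero-conc reference.

    Member seeds are derived deterministically from ``seed``, so identical
    seeds give bit-identical sets.
    """
    concs = tuple(float(c) for c in concs)
    if not concs:
        raise InvalidInputError("need at least one concentration")
    if len(set(concs)) != len(concs):
        raise InvalidInputError("duplicate concentrations in series")
    if any(c <= 0 for c in concs):
        raise InvalidInputError("series concentrations must be > 0")
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    schedule = schedule or PhaseSchedule()
    n = len(concs) * replicates + 1
    seeds = _child_seeds(seed, n)
    grams = []
    k = 0
    for rep in range(1, replicates + 1):
        for c in concs:
            grams.append(
                simulate_sensorgram(
                    params, c, schedule, noise, seed=seeds[k],
                    sensor_id=f"c{c * 1e9:g}nM_rep{rep}",
                )
            )
            k += 1
    grams.append(
        simulate_sensorgram(params, 0.0, schedule, noise, seed=seeds[k],
                            sensor_id="reference")
    )
    return SensorgramSet(sensorgrams=grams, truth=params, seed=seed)


# ---------------------------------------------------------------------------
# promoter panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedOperator:
    """Ground truth for one planted operator instance.

    ``instance`` is the pattern-matching string; on the minus strand the
    promoter carries its reverse complement at ``start``.
    """

    start: int
    strand: str
    instance: str


@dataclass
class PromoterRecord:
    """A synthetic upstream region with planted-operator ground truth."""

    id: str
    sequence: str
    operators: list[PlantedOperator] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_operators(self) -> int:
        return len(self.operators)


def sample_from_pattern(pattern: DegeneratePattern | str, seed=0) -> str:
    """Draw one concrete instance, uniform within each position's allowed set.

    ``seed`` may also be a numpy Generator.
    """
    pattern = compile_pattern(pattern) if isinstance(pattern, str) else pattern
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(sorted(s)[rng.integers(len(s))] for s in pattern.allowed_sets)


def triangular_gap_sampler(low: int = 24, mode: int = 26, high: int = 39):
    """Discrete triangular sampler on [low, high] peaked at ``mode``.

    Weights rise linearly to 1 at the mode and fall linearly to 1/(high-mode+1)
    at ``high``; this emulates an inter-operator gap distribution spanning
    24-39 bases with modal gap 26.
    """
    if not low <= mode <= high:
        raise InvalidInputError("need low <= mode <= high")
    gaps = np.arange(low, high + 1)
    w = np.where(
        gaps <= mode,
        (gaps - low + 1) / (mode - low + 1),
        (high - gaps + 1) / (high - mode + 1),
    ).astype(float)
    w /= w.sum()

    def sampler(rng: np.random.Generator) -> int:
        return int(rng.choice(gaps, p=w))

    sampler.support = gaps  # type: ignore[attr-defined]
    sampler.weights = w  # type: ignore[attr-defined]
    return sampler


def _planted_hits_ok(
    hits: list[OperatorHit], planted: list[PlantedOperator]
) -> bool:
    """Scan must find hits only at planted starts, with planted strands present.

    A near-palindromic instance legitimately matches both strands at the same
    start; such duplicates are tolerated (they collapse to one physical site
    downstream).
    """
    starts = {p.start for p in planted}
    if any(h.start not in starts for h in hits):
        return False
    found = {(h.start, h.strand) for h in hits}
    return all((p.start, p.strand) in found for p in planted)


def generate_promoter(
    length: int = 100,
    n_operators: int = 1,
    gap=None,
    strand_choice: str = "random",
    pattern: DegeneratePattern | str = PRESETS["FAMILY_16"],
    seed: int = 0,
    promoter_id: str | None = None,
    max_attempts: int = 10_000,
) -> PromoterRecord:
    """Generate one promoter with exactly ``n_operators`` planted instances.

    ``gap`` (two-operator records only) is an int or a ``sampler(rng) -> int``;
    by default gaps are drawn from :func:`triangular_gap_sampler`.  The whole
    record is rejection-sampled until a both-strand scan finds exactly the
    planted sites, so spurious background matches never occur.
    """
    pattern = compile_pattern(pattern) if isinstance(pattern, str) else pattern
    if n_operators not in (0, 1, 2):
        raise InvalidInputError("n_operators must be 0, 1 or 2")
    if strand_choice not in ("+", "-", "random"):
        raise InvalidInputError(f"invalid strand_choice {strand_choice!r}")
    L = len(pattern)
    if n_operators >= 1 and length < L:
        raise InvalidInputError("sequence shorter than pattern")
    if n_operators == 2 and isinstance(gap, (int, np.integer)):
        if 2 * L + int(gap) > length:
            raise InvalidInputError("operators + gap exceed sequence length")
    gap_sampler = None
    if n_operators == 2:
        if gap is None:
            gap_sampler = triangular_gap_sampler()
        elif callable(gap):
            gap_sampler = gap

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        if n_operators == 2:
            g = int(gap_sampler(rng)) if gap_sampler is not None else int(gap)
            if 2 * L + g > length:
                raise InvalidInputError("operators + gap exceed sequence length")
        planted: list[PlantedOperator] = []
        seq = rng.choice(bases, size=length)
        if n_operators == 1:
            start = int(rng.integers(0, length - L + 1))
            starts = [start]
        elif n_operators == 2:
            start = int(rng.integers(0, length - (2 * L + g) + 1))
            starts = [start, start + L + g]
        else:
            starts = []
        for s0 in starts:
            strand = (
                strand_choice
                if strand_choice in "+-"
                else ("+", "-")[rng.integers(2)]
            )
            instance = sample_from_pattern(pattern, rng)
            embedded = instance if strand == "+" else reverse_complement(instance)
            seq[s0 : s0 + L] = list(embedded)
            planted.append(PlantedOperator(start=s0, strand=strand, instance=instance))
        sequence = "".join(seq)
        hits = scan(sequence, pattern, max_mismatch=0, strands="both")
        if _planted_hits_ok(hits, planted):
            return PromoterRecord(
                id=promoter_id or f"prom_{n_operators}op_seed{seed}",
                sequence=sequence,
                operators=planted,
                gaps=[b.start - (a.start + L) for a, b in zip(planted, planted[1:])],
                seed=seed,
            )
    raise RuntimeError(
        f"no spurious-match-free promoter found in {max_attempts} attempts"
    )


def generate_panel(
    composition: dict[int, int],
    gap_sampler=None,
    pattern: DegeneratePattern | str = PRESETS["FAMILY_16"],
    seed: int = 0,
    length: int = 100,
    strand_choice: str = "random",
) -> list[PromoterRecord]:
    """Generate a promoter panel, e.g. ``{2: 67, 1: 14, 0: 7}``.

    Gaps for two-operator records come from ``gap_sampler`` (default
    triangular on 24-39 peaked at 26); per-record sub-seeds are derived from
    ``seed``, so the panel is reproducible.
    """
    if any(c < 0 for c in composition.values()):
        raise InvalidInputError("composition counts must be >= 0")
    total = sum(composition.values())
    seeds = _child_seeds(seed, max(total, 1))
    records: list[PromoterRecord] = []
    k = 0
    for n_ops in sorted(composition, reverse=True):
        for i in range(composition[n_ops]):
            records.append(
                generate_promoter(
                    length=length,
                    n_operators=n_ops,
                    gap=gap_sampler if n_ops == 2 else None,
                    strand_choice=strand_choice,
                    pattern=pattern,
                    seed=seeds[k],
                    promoter_id=f"prom_{n_ops}op_{i + 1:03d}",
                )
            )
            k += 1
    return records
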