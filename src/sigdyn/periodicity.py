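"""Nucleosome-relative mutation-rate periodicity.

Mutations are stacked on nucleosome dyad centres (signed offsets, +-72 bp
zoom-in or +-1000 bp zoom-out). The expected profile under no positional
preference is the mean over pentamer-preserving randomizations: each
mutation is relocated to a uniformly random position with the identical
pyrimidine-oriented pentamer within the stacked windows, which conserves
sequence-composition structure exactly. The relative increase
r(x) = (observed - expected)/expected is mean-centred (zoom-out profiles
are additionally detrended with a 50-bp moving average) and transformed
with an oversampled discrete-time Fourier periodogram over periods 5-50 bp
in 0.01 bp steps; a plain DFT on ~145 offsets cannot resolve a 10.3 bp
from a 10.15 bp helical repeat, hence the oversampling. The
signal-to-noise ratio is the peak power over the median power of the rest
of the band, and the empirical p-value compares the observed SNR against
the SNRs of the randomized sets pushed through the identical chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._channels import fold_pyrimidine
from .catalogue import ContextualizedSNV
from .genome import ArgumentError, SyntheticGenome

DEFAULT_BAND = (5.0, 50.0)
DEFAULT_STEP = 0.01
SNR_EXCLUDE_BP = 0.5
ZOOM_IN = 72
ZOOM_OUT = 1000
DETREND_WINDOW = 50


@dataclass
class StackedProfile:
    """Observed/expected mutation counts per signed dyad offset."""

    offsets: np.ndarray  # -window..window
    observed: np.ndarray
    expected: np.ndarray  # mean over randomizations

    @property
    def mask(self) -> np.ndarray:
        """Offsets usable for the relative increase (expected > 0)."""
        return self.expected > 0

    def relative_increase(self) -> np.ndarray:
        """(observed - expected)/expected on unmasked offsets (NaN elsewhere)."""
        r = np.full(len(self.offsets), np.nan)
        m = self.mask
        r[m] = (self.observed[m] - self.expected[m]) / self.expected[m]
        return r


@dataclass
class PeriodicityResult:
    period_grid: np.ndarray
    power: np.ndarray
    max_power_period: float
    snr: float
    empirical_p: float | None = None
    n_randomizations: int = 0


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def stack_mutations(
    snvs: list[ContextualizedSNV] | list[tuple[str, int]],
    dyads: dict[str, np.ndarray],
    window: int = ZOOM_IN,
) -> np.ndarray:
    """Counts per signed offset for mutations within ``window`` of any dyad.

    A mutation within the window of several dyads contributes at each
    qualifying offset, so the total equals the number of (mutation, dyad)
    incidences.
    """
    if not dyads or all(len(d) == 0 for d in dyads.values()):
        raise ArgumentError("no dyads provided")
    positions: dict[str, list[int]] = {}
    for s in snvs:
        chrom, pos = (s.variant.chrom, s.variant.pos) if isinstance(s, ContextualizedSNV) else s
        positions.setdefault(chrom, []).append(pos)
    counts = np.zeros(2 * window + 1, dtype=np.int64)
    for chrom, pos_list in positions.items():
        dy = dyads.get(chrom)
        if dy is None or len(dy) == 0:
            continue
        pos = np.asarray(pos_list, dtype=np.int64)
        lo = np.searchsorted(dy, pos - window, side="left")
        hi = np.searchsorted(dy, pos + window, side="right")
        for p, a, b in zip(pos, lo, hi):
            if b > a:
                np.add.at(counts, (p - dy[a:b]) + window, 1)
    return counts


def in_window(
    snvs: list[ContextualizedSNV], dyads: dict[str, np.ndarray], window: int = ZOOM_IN
) -> list[ContextualizedSNV]:
    """Mutations lying within ``window`` bp of at least one dyad."""
    out = []
    for s in snvs:
        dy = dyads.get(s.variant.chrom)
        if dy is None or len(dy) == 0:
            continue
        i = int(np.searchsorted(dy, s.variant.pos))
        for k in (i - 1, i):
            if 0 <= k < len(dy) and abs(s.variant.pos - dy[k]) <= window:
                out.append(s)
                break
    return out


# ---------------------------------------------------------------------------
# pentamer-preserving randomization
# ---------------------------------------------------------------------------

class PentamerRandomizer:
    """Relocate mutations uniformly among same-pentamer window positions.

    The index covers the union of ``+-window`` regions around dyads; each
    position is keyed by its pyrimidine-oriented pentamer. Because every
    indexed position lies in a window at a known dyad offset, a randomized
    set can be stacked directly from precomputed offsets.
    """

    def __init__(self, genome: SyntheticGenome, dyads: dict[str, np.ndarray], window: int = ZOOM_IN):
        self.window = window
        per_pent: dict[str, list[tuple[int, int, int]]] = {}
        chrom_code = {c: i for i, c in enumerate(genome.sequences)}
        for chrom, dy in dyads.items():
            if chrom not in genome.sequences:
                continue
            seq = genome.sequences[chrom]
            seen_upto = -1
            for d in dy:
                start = max(int(d) - window, 2, seen_upto + 1)
                end = min(int(d) + window + 1, len(seq) - 2)
                seen_upto = end - 1
                for p in range(start, end):
                    pent = seq[p - 2 : p + 3]
                    if "N" in pent:
                        continue
                    per_pent.setdefault(fold_pyrimidine(pent), []).append(
                        (chrom_code[chrom], p, p - int(d))
                    )
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for pent, triples in per_pent.items():
            arr = np.array(triples, dtype=np.int64)
            self._index[pent] = (arr[:, 0], arr[:, 1], arr[:, 2])
        self._chrom_names = list(genome.sequences)

    def candidate_counts(self) -> dict[str, int]:
        return {p: len(v[0]) for p, v in self._index.items()}

    def group_counts(self, snvs: list[ContextualizedSNV]) -> tuple[dict[str, int], int]:
        """Pentamer multiset of relocatable mutations, plus the number whose
        pentamer has no indexed candidate position (kept in place)."""
        groups: dict[str, int] = {}
        skipped = 0
        for s in snvs:
            if s.pentamer is None or s.pentamer not in self._index:
                skipped += 1
                continue
            groups[s.pentamer] = groups.get(s.pentamer, 0) + 1
        return groups, skipped

    def randomize(self, snvs: list[ContextualizedSNV], seed: int = 0) -> list[tuple[str, int]]:
        """One randomized mutation set as (chrom, pos) pairs."""
        rng = np.random.default_rng(seed)
        out: list[tuple[str, int]] = []
        for s in snvs:
            if s.pentamer is None or s.pentamer not in self._index:
                out.append((s.variant.chrom, s.variant.pos))
                continue
            codes, pos, _ = self._index[s.pentamer]
            i = int(rng.integers(len(pos)))
            out.append((self._chrom_names[codes[i]], int(pos[i])))
        return out

    def randomized_offset_counts(
        self, snvs: list[ContextualizedSNV], n_rand: int, seed: int = 0
    ) -> np.ndarray:
        """Stacked offset counts of ``n_rand`` randomized sets,
        shape (n_rand, 2*window+1)."""
        rng = np.random.default_rng(seed)
        w = self.window
        width = 2 * w + 1
        counts = np.zeros((n_rand, width), dtype=np.int64)
        groups, _ = self.group_counts(snvs)
        for pent, n_mut in groups.items():
            _, _, offs = self._index[pent]
            draws = rng.integers(len(offs), size=(n_rand, n_mut))
            sel = offs[draws] + w
            flat = (np.arange(n_rand)[:, None] * width + sel).ravel()
            counts += np.bincount(flat, minlength=n_rand * width).reshape(n_rand, width)
        return counts


# ---------------------------------------------------------------------------
# periodogram
# ---------------------------------------------------------------------------

def _signal_rows(R: np.ndarray, window: int) -> np.ndarray:
    """Detrend (zoom-out only) and mean-centre relative-increase rows.

    ``R`` is (k, n_offsets) with NaN at masked offsets; masked entries are
    zeroed after centring so they drop out of the explicit Fourier sums.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    valid = np.isfinite(R)
    if not valid.any(axis=1).all():
        raise ArgumentError("all offsets masked; no usable relative increase")
    Y = np.where(valid, R, 0.0)
    if window > ZOOM_IN:
        means = Y.sum(axis=1, keepdims=True) / valid.sum(axis=1, keepdims=True)
        filled = np.where(valid, R, means)
        trend = uniform_filter1d(filled, size=DETREND_WINDOW, axis=1, mode="nearest")
        Y = np.where(valid, filled - trend, 0.0)
    means = Y.sum(axis=1, keepdims=True) / valid.sum(axis=1, keepdims=True)
    return np.where(valid, Y - means, 0.0)


def _phases(offsets: np.ndarray, periods: np.ndarray) -> np.ndarray:
    return np.exp(-2j * np.pi * np.outer(offsets.astype(float), 1.0 / periods))


def periodogram_power(x: np.ndarray, y: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """|sum_x y(x) exp(-2*pi*i*x/T)|^2 by explicit sums (oversampled DTFT)."""
    return np.abs(y @ _phases(np.asarray(x), np.asarray(periods, dtype=float))) ** 2


def _snr(periods: np.ndarray, power: np.ndarray) -> tuple[float, float]:
    i = int(np.argmax(power))
    mp = float(periods[i])
    background = power[np.abs(periods - mp) > SNR_EXCLUDE_BP]
    med = float(np.median(background)) if len(background) else np.nan
    return mp, float(power[i] / med) if med > 0 else float("inf")


def periodogram(
    profile: StackedProfile,
    band: tuple[float, float] = DEFAULT_BAND,
    step: float = DEFAULT_STEP,
) -> PeriodicityResult:
    """Oversampled periodogram of the mean-centred relative increase."""
    periods = np.arange(band[0], band[1] + step / 2, step)
    window = (len(profile.offsets) - 1) // 2
    y = _signal_rows(profile.relative_increase(), window)[0]
    power = periodogram_power(profile.offsets, y, periods)
    mp, snr = _snr(periods, power)
    return PeriodicityResult(periods, power, mp, snr)


# ---------------------------------------------------------------------------
# full chain with empirical p
# ---------------------------------------------------------------------------

@dataclass
class PeriodicityAnalysis:
    profile: StackedProfile
    result: PeriodicityResult
    n_stacked: int
    randomized_snrs: np.ndarray | None = None


def analyze_periodicity(
    snvs: list[ContextualizedSNV],
    genome: SyntheticGenome,
    dyads: dict[str, np.ndarray] | None = None,
    window: int = ZOOM_IN,
    n_rand: int = 1000,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    step: float = DEFAULT_STEP,
    compute_p: bool = True,
    randomizer: PentamerRandomizer | None = None,
) -> PeriodicityAnalysis:
    """Stack -> randomize -> relative increase -> periodogram -> empirical p.

    The expected profile is the mean of ``n_rand`` pentamer-preserving
    randomizations. For the empirical p-value each randomized set is pushed
    through the identical chain, with the leave-one-out mean of the other
    randomizations as its expected profile, and
    p = (1 + #{randomized SNR >= observed SNR}) / (1 + n_rand). A
    prebuilt ``randomizer`` (the expensive index) may be reused.
    """
    if compute_p and n_rand < 100:
        raise ArgumentError("empirical p needs at least 100 randomizations")
    dyads = dyads if dyads is not None else genome.dyads
    if randomizer is None:
        randomizer = PentamerRandomizer(genome, dyads, window)
    offsets = np.arange(-window, window + 1)
    periods = np.arange(band[0], band[1] + step / 2, step)

    # only mutations inside the stacked windows take part; the randomized
    # sets must be relocations of exactly the observed set
    snvs = in_window(snvs, dyads, window)
    observed = stack_mutations(snvs, dyads, window)
    rand_counts = randomizer.randomized_offset_counts(snvs, n_rand, seed)
    expected = rand_counts.mean(axis=0)
    profile = StackedProfile(offsets, observed, expected)

    phases = _phases(offsets, periods)
    y_obs = _signal_rows(profile.relative_increase(), window)[0]
    power = np.abs(y_obs @ phases) ** 2
    mp, snr = _snr(periods, power)
    result = PeriodicityResult(periods, power, mp, snr)

    snrs = None
    if compute_p:
        total = rand_counts.sum(axis=0)
        exp_loo = (total[None, :] - rand_counts) / (n_rand - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(exp_loo > 0, (rand_counts - exp_loo) / exp_loo, np.nan)
        Y = _signal_rows(R, window)
        P = np.abs(Y @ phases) ** 2
        snrs = np.empty(n_rand)
        for k in range(n_rand):
            _, snrs[k] = _snr(periods, P[k])
        result.empirical_p = (1 + int(np.sum(snrs >= snr))) / (1 + n_rand)
        result.n_randomizations = n_rand
    return PeriodicityAnalysis(profile=profile, result=result,
                               n_stacked=int(observed.sum()), randomized_snrs=snrs)


def empirical_p(
    observed_snr: float,
    snvs: list[ContextualizedSNV],
    genome: SyntheticGenome,
    dyads: dict[str, np.ndarray] | None = None,
    window: int = ZOOM_IN,
    n_rand: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p of an SNR against the pentamer-randomization null."""
    analysis = analyze_periodicity(
        snvs, genome, dyads, window=window, n_rand=n_rand, seed=seed, compute_p=True
    )
    count = int(np.sum(analysis.randomized_snrs >= observed_snr))
    return (1 + count) / (1 + n_rand)
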