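"""Surrogate null conditions: pseudo-dyads and segment shuffling.

Pseudo-dyads pair participant 1 of one take with participant 2 of every
take from a *different* real dyad (ordered pairings); unequal series are
truncated, from t = 0, to the shorter length.  Segment shuffling cuts one
series of a pair into fixed-length segments (200 ms by default) and
permutes them in time, destroying cross-signal alignment while keeping
the sample multiset — and hence the marginal distribution — intact.

Per-surrogate band summaries are averaged at the level of the real dyad
they are assigned to (the dyad contributing the participant-1 slot for
pseudo-dyads; the dyad itself for segment shuffles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .circular_stats import AngleSample, circular_mean
from .series import UniformSeries
from .wavelet_sync import (
    BandStats,
    BandSummary,
    TimescaleBands,
    WaveletParams,
    coherence_and_phase,
    band_average,
    cwt_morlet,
    default_bands,
)

__all__ = [
    "TakeSeries",
    "PseudoDyadPlan",
    "SurrogateEnsemble",
    "plan_pseudo_dyads",
    "segment_shuffle",
    "pseudo_dyad_ensemble",
    "segment_shuffle_ensemble",
    "surrogate_band_distribution",
    "average_band_summaries",
]

DEFAULT_SEGMENT_S = 0.200
DEFAULT_N_SHUFFLES = 200


@dataclass(frozen=True)
class TakeSeries:
    """One take's pair of series for a given pair spec.

    ``first`` is the participant-1-slot series, ``second`` the
    participant-2-slot series of the same take.
    """

    take_id: str
    dyad_id: str
    first: UniformSeries
    second: UniformSeries


@dataclass(frozen=True)
class Pairing:
    """One pseudo-dyad: P1 of ``first_take`` with P2 of ``second_take``."""

    first_take: str
    second_take: str
    truncation: int  # samples


@dataclass
class PseudoDyadPlan:
    """All valid ordered pseudo-dyad pairings for a set of takes."""

    pairings: list[Pairing]

    def __len__(self) -> int:
        return len(self.pairings)


def plan_pseudo_dyads(takes: Sequence[TakeSeries]) -> PseudoDyadPlan:
    """All ordered pairings (P1 of take i, P2 of take j) across real dyads.

    Pairings drawing both members from the same real dyad are excluded.
    For ``n`` takes all from distinct dyads this yields ``n * (n - 1)``
    pairings.  Truncation length is the min of the two series lengths.
    """
    if len(takes) < 2:
        raise ValueError(f"need at least 2 takes, got {len(takes)}")
    pairings = []
    for ti in takes:
        for tj in takes:
            if ti.take_id == tj.take_id or ti.dyad_id == tj.dyad_id:
                continue
            pairings.append(
                Pairing(
                    ti.take_id,
                    tj.take_id,
                    min(len(ti.first), len(tj.second)),
                )
            )
    return PseudoDyadPlan(pairings)


def segment_shuffle(
    s: UniformSeries,
    segment_s: float = DEFAULT_SEGMENT_S,
    rng_seed: int | np.random.Generator = 0,
    drop_remainder: bool = False,
) -> UniformSeries:
    """Permute consecutive fixed-length segments of a series in time.

    Segments are ``round(segment_s * rate)`` samples; a final shorter
    remainder is kept and shuffled with the rest (or dropped when
    ``drop_remainder`` is True).  The permutation is drawn uniformly from
    the seeded generator; the sample multiset is preserved.
    """
    if not segment_s > 0:
        raise ValueError(f"segment_s must be > 0, got {segment_s}")
    seg_len = int(round(segment_s * s.rate))
    if seg_len < 1:
        raise ValueError(
            f"segment of {segment_s:g}s is shorter than one sample at "
            f"{s.rate:g} Hz"
        )
    n = len(s)
    if n <= seg_len and drop_remainder and n < seg_len:
        raise ValueError("series shorter than one segment with drop_remainder")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_full = n // seg_len
    segments = [s.values[i * seg_len : (i + 1) * seg_len] for i in range(n_full)]
    remainder = s.values[n_full * seg_len :]
    if remainder.size and not drop_remainder:
        segments.append(remainder)
    order = rng.permutation(len(segments))
    out = np.concatenate([segments[i] for i in order]) if segments else s.values[:0]
    return UniformSeries(out, s.rate, s.start, s.label)


@dataclass
class SurrogateEnsemble:
    """Distribution of band summaries under one null condition."""

    condition: str  # "pseudo_dyad" | "segment_shuffle"
    summaries: list[tuple[str, BandSummary]]  # (assigned dyad id, summary)
    dyad_means: dict[str, BandSummary]
    n: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def band_values(self, lo: float, hi: float) -> np.ndarray:
        """Per-surrogate mean coherence in one band (NaN if missing)."""
        return np.array(
            [s.band(lo, hi).mean_coherence for _, s in self.summaries]
        )


def average_band_summaries(
    summaries: Sequence[BandSummary], pair: str = "", level: str = "", modality_class: str = ""
) -> BandSummary:
    """Band-wise average: arithmetic for coherence, circular for phase.

    Bands missing in every input stay missing; missing entries are
    excluded from the averages of the others.
    """
    if not summaries:
        raise ValueError("cannot average an empty list of summaries")
    n_bands = len(summaries[0].bands)
    out: list[BandStats] = []
    for k in range(n_bands):
        ref = summaries[0].bands[k]
        entries = [s.bands[k] for s in summaries if not s.bands[k].missing]
        if not entries:
            out.append(BandStats(ref.lo, ref.hi, float("nan"), float("nan"), float("nan"), 0))
            continue
        coh = float(np.mean([b.mean_coherence for b in entries]))
        phases = np.array([b.circ_mean_phase_deg for b in entries])
        ok = np.isfinite(phases)
        if ok.any():
            cm = circular_mean(AngleSample(phases[ok]))
            ph, r = cm.mean_deg, cm.resultant_length
        else:
            ph, r = float("nan"), float("nan")
        out.append(
            BandStats(ref.lo, ref.hi, coh, ph, r, int(sum(b.n_valid_bins for b in entries)))
        )
    return BandSummary(pair=pair, level=level, modality_class=modality_class, bands=out)


class _SpectrumCache:
    """CWT results keyed by (series identity, truncation length).

    The cached series object is stored alongside its spectrum: holding the
    reference keeps ``id()`` keys unique for the cache's lifetime.
    """

    def __init__(self, params: WaveletParams):
        self.params = params
        self.grid = params.grid()
        self._store: dict[tuple[int, int], tuple[UniformSeries, object]] = {}

    def compute(self, s: UniformSeries, n: int):
        trunc = (
            s if n == len(s) else UniformSeries(s.values[:n], s.rate, s.start, s.label)
        )
        return cwt_morlet(trunc, self.grid, self.params.omega0)

    def get(self, s: UniformSeries, n: int):
        key = (id(s), n)
        if key not in self._store:
            self._store[key] = (s, self.compute(s, n))
        return self._store[key][1]


def _pair_summary_cached(
    cache: _SpectrumCache,
    sa: UniformSeries,
    sb: UniformSeries,
    n: int,
    bands: TimescaleBands,
    **meta,
) -> BandSummary:
    wa = cache.get(sa, n)
    wb = cache.get(sb, n)
    coh, ph = coherence_and_phase(wa, wb, cache.params)
    return band_average(coh, ph, bands, exclude_coi=cache.params.exclude_coi, **meta)


def pseudo_dyad_ensemble(
    takes: Sequence[TakeSeries],
    params: WaveletParams | None = None,
    bands: TimescaleBands | None = None,
    *,
    max_per_dyad: int | None = None,
    seed: int = 0,
    pair: str = "",
    level: str = "inter",
    modality_class: str = "",
) -> SurrogateEnsemble:
    """Band summaries over all pseudo-dyad pairings, averaged per real dyad.

    ``max_per_dyad`` randomly subsamples (seeded) the pairings assigned to
    each dyad; by default all pairings are analysed.
    """
    params = params or WaveletParams()
    bands = bands or default_bands()
    plan = plan_pseudo_dyads(takes)
    if not plan.pairings:
        raise ValueError("pseudo-dyad plan is empty (all takes share a dyad?)")
    by_take = {t.take_id: t for t in takes}
    by_dyad: dict[str, list[Pairing]] = {}
    for p in plan.pairings:
        by_dyad.setdefault(by_take[p.first_take].dyad_id, []).append(p)
    rng = np.random.default_rng(seed)
    cache = _SpectrumCache(params)
    summaries: list[tuple[str, BandSummary]] = []
    dyad_means: dict[str, BandSummary] = {}
    meta = dict(pair=pair, level=level, modality_class=modality_class)
    for dyad_id in sorted(by_dyad):
        pairings = by_dyad[dyad_id]
        if max_per_dyad is not None and len(pairings) > max_per_dyad:
            idx = rng.choice(len(pairings), size=max_per_dyad, replace=False)
            pairings = [pairings[i] for i in sorted(idx)]
        per_dyad = []
        for p in pairings:
            summ = _pair_summary_cached(
                cache,
                by_take[p.first_take].first,
                by_take[p.second_take].second,
                p.truncation,
                bands,
                **meta,
            )
            per_dyad.append(summ)
            summaries.append((dyad_id, summ))
        dyad_means[dyad_id] = average_band_summaries(per_dyad, **meta)
    return SurrogateEnsemble(
        condition="pseudo_dyad",
        summaries=summaries,
        dyad_means=dyad_means,
        n=len(summaries),
        seed=seed,
        meta={"n_takes": len(takes), "n_pairings_total": len(plan.pairings)},
    )


def segment_shuffle_ensemble(
    pairs: Mapping[str, tuple[UniformSeries, UniformSeries]],
    params: WaveletParams | None = None,
    bands: TimescaleBands | None = None,
    *,
    n_surrogates: int = DEFAULT_N_SHUFFLES,
    segment_s: float = DEFAULT_SEGMENT_S,
    seed: int = 0,
    pair: str = "",
    level: str = "intra",
    modality_class: str = "",
) -> SurrogateEnsemble:
    """Within-subject null: shuffle the second-named series of each pair.

    Only one member is shuffled so the comparison keeps the first series'
    structure intact; ``n_surrogates`` shuffles per dyad, averaged per dyad.
    """
    params = params or WaveletParams()
    bands = bands or default_bands()
    if not pairs:
        raise ValueError("no pairs given")
    cache = _SpectrumCache(params)
    rng = np.random.default_rng(seed)
    meta = dict(pair=pair, level=level, modality_class=modality_class)
    summaries: list[tuple[str, BandSummary]] = []
    dyad_means: dict[str, BandSummary] = {}
    for dyad_id in sorted(pairs):
        sa, sb = pairs[dyad_id]
        n = min(len(sa), len(sb))
        per_dyad = []
        wa = cache.get(sa, n)
        for _ in range(n_surrogates):
            shuffled = segment_shuffle(
                UniformSeries(sb.values[:n], sb.rate, sb.start, sb.label),
                segment_s,
                rng,
            )
            wb = cache.compute(shuffled, n)  # one-shot, not cached
            coh, ph = coherence_and_phase(wa, wb, cache.params)
            summ = band_average(
                coh, ph, bands, exclude_coi=cache.params.exclude_coi, **meta
            )
            per_dyad.append(summ)
            summaries.append((dyad_id, summ))
        dyad_means[dyad_id] = average_band_summaries(per_dyad, **meta)
    return SurrogateEnsemble(
        condition="segment_shuffle",
        summaries=summaries,
        dyad_means=dyad_means,
        n=len(summaries),
        seed=seed,
        meta={"segment_s": segment_s, "n_surrogates": n_surrogates},
    )


def surrogate_band_distribution(
    *,
    condition: str,
    takes: Sequence[TakeSeries] | None = None,
    pairs: Mapping[str, tuple[UniformSeries, UniformSeries]] | None = None,
    params: WaveletParams | None = None,
    bands: TimescaleBands | None = None,
    n_surrogates: int | None = None,
    segment_s: float = DEFAULT_SEGMENT_S,
    seed: int = 0,
    **meta,
) -> SurrogateEnsemble:
    """Dispatch to the pseudo-dyad or segment-shuffle ensemble builder."""
    if condition == "pseudo_dyad":
        if takes is None:
            raise ValueError("pseudo_dyad condition requires takes=")
        return pseudo_dyad_ensemble(
            takes, params, bands, max_per_dyad=n_surrogates, seed=seed, **meta
        )
    if condition == "segment_shuffle":
        if pairs is None:
            raise ValueError("segment_shuffle condition requires pairs=")
        return segment_shuffle_ensemble(
            pairs,
            params,
            bands,
            n_surrogates=n_surrogates or DEFAULT_N_SHUFFLES,
            segment_s=segment_s,
            seed=seed,
            **meta,
        )
    raise ValueError(
        f"unknown condition {condition!r}; expected pseudo_dyad or segment_shuffle"
    )
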