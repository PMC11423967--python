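# dyadsync

Multiscale synchrony analysis for dyadic face-to-face conversation.

The package turns per-participant motion capture (BVH), audio (WAV) and
speaking-time annotations (TSV tiers) into three analysis series per
participant — head speed, summed wrist speed and voice amplitude envelope —
on a common 90 Hz clock, then quantifies intra- and interpersonal
coordination with Morlet cross-wavelet coherence and relative phase,
aggregated over 23 timescale bands from 0.125 s to 30 s. Conversational
structure (speech units, pauses, gaps, turns, overlaps, turn switches) is
segmented from the tiers. Significance is assessed against two surrogate
nulls — pseudo-dyads (between-subject shuffling) and 200 ms segment
shuffling (within-subject) — with per-band sign-flip permutation tests and
Bonferroni correction across bands. A synthetic dyad generator with known
turn statistics and per-band coupling/phase-lag ground truth makes every
stage testable without any external dataset.

## Layout

| module | role |
| --- | --- |
| `dyadsync.io_formats` | BVH parsing + forward kinematics, WAV, tier TSV, result tables |
| `dyadsync.signal_prep` | Butterworth filtering, speeds, Hilbert envelope, resampling |
| `dyadsync.turn_taking` | speech units / pauses / gaps / turns / overlaps / switches |
| `dyadsync.wavelet_sync` | Morlet CWT, cross-wavelet coherence & phase, band averages |
| `dyadsync.circular_stats` | wrapping, circular mean, circular histogram, peak angle |
| `dyadsync.surrogates` | pseudo-dyad and segment-shuffle ensembles |
| `dyadsync.pipeline_cli` | full-run orchestration, permutation tests, `dyadsync` CLI |
| `dyadsync.synthetic_data` | ground-truth dyad simulator |

## CLI

```sh
# simulate a session (tiers + six series + ground-truth structure)
dyadsync simulate --duration 300 --seed 7 --out sessions/dyad0

# segment a tier file into turns/overlaps/switches
dyadsync turns --tiers sessions/dyad0/tiers.tsv --min-silence 0.2 --out structure.json

# cross-wavelet band summary of two series files
dyadsync xwt --a sessions/dyad0/A_head_speed.tsv --b sessions/dyad0/B_head_speed.tsv --out bands.tsv

# full synthetic-dyad analysis (all 9 pair types, both surrogate conditions)
dyadsync run --dyads 6 --duration 120 --seed 1 --out results/run1

# surrogate ensembles over simulated sessions
dyadsync surrogates --condition pseudo --session-dir sessions/dyad0 \
    --session-dir sessions/dyad1 --out ensemble.tsv
```

`dyadsync run --config run.toml` accepts a TOML file with keys
`n_dyads, duration_s, rate, seed, n_shuffles, n_perm, segment_s` and
`[[couplings]]` tables (`target, driver, band_s, strength, lag_deg`).

## Conventions

* Relative phase is reported in degrees in [-180, 180); positive phase
  means the first-named series leads.
* Timescale bands are half-open `(lo, hi]` in wavelet period.
* Speech-unit merging uses silence < 200 ms (strict); silences of exactly
  the threshold separate.
* Coherence smoothing (scale-matched Gaussian in time, 0.6-octave boxcar
  across scales) is part of the coherence definition; all parameters are
  exposed via `WaveletParams`.
* Cone-of-influence bins are excluded from band averages by default
  (`WaveletParams.exclude_coi`).
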