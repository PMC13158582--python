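# proxrange

Animal space use from proximity-biologging detection grids.

Proximity loggers record *encounters* — a tag heard by a receiver, with a
timestamp and a received signal strength (RSSI) — rather than locations.
When the receivers form a fixed grid, those encounters still carry spatial
information: every detection places the animal within the receiving
station's detection range, and the RSSI splits that range into coarse
distance bands. `proxrange` turns per-station encounter logs into
utilization distributions (UDs) and overlap analyses for small,
site-faithful animals (the motivating system is a maternity colony of
Bechstein's bats monitored by a 65-station Bluetooth low-energy grid),
and ships a simulator to validate the whole chain against reference GPS
tracks.

## Pipeline

1. **Localization.** Records at or below the −90 dBm noise floor are
   discarded. Each surviving record becomes a *fix* drawn uniformly over
   the area of its RSSI band around the station: a 15 m disc for records
   ≥ −82 dBm, a 15–35 m annulus below that. Nightly activity windows
   (schedule 21:00–05:00, trimmed to 2 h after sunset and 3 h before
   sunrise) remove roost-related activity.
2. **UD estimation.** Fixes arrive every ~2 s and are strongly
   autocorrelated, so a classic kernel density estimate would
   undersmooth. `proxrange` fits independent-Gaussian (IID) and
   Ornstein–Uhlenbeck (OU) position models by exact maximum likelihood,
   selects by AIC, converts the fitted timescale τ into an effective
   sample size n_eff = T/τ (T = monitored time), and uses the Gaussian
   reference bandwidth h_i = σ̂_i · n_eff^(−1/6) per axis. The 95%
   isopleth of the resulting raster is the home range, the 50% isopleth
   the core area.
3. **Overlap.** Dyadic space sharing, kinship contrasts and site fidelity
   use two symmetric indices on a common raster: Bhattacharyya's affinity
   BA = ∫∫ √(UD_a·UD_b) ∈ [0, 1] and the utilization distribution overlap
   index UDOI = A_overlap·∫∫ UD_a·UD_b (1 for identical uniform use, > 1
   for shared concentration). By default each UD is conditioned on
   (truncated to and renormalized within) its own isopleth level first.
4. **Validation.** The simulator builds the station lattice, OU movement
   with per-individual home-range centers, a log-distance RSSI model
   calibrated so −82 dBm falls at 15 m and −90 dBm at 40 m
   (P₀ ≈ −59.9 dBm, γ ≈ 1.88), and 45-minute walking tracks observed
   simultaneously by GPS and by the grid — the design used in the field
   to quantify locational accuracy.

## Worked example

Simulate a two-night tagging batch of six bats (one mother–daughter pair)
on the default 65-station grid, localize, estimate UDs and contrast
overlap by kinship:

```sh
proxrange simulate --scenario colony --seed 1 --interval 10 -o sim
proxrange fixes --logs sim/logs --stations sim/stations.csv --seed 1 \
    --sun-table sim/sun_table.csv -o fixes.csv
proxrange ud --fixes fixes.csv -o uds
proxrange overlap --ud-dir uds --kinship sim/kinship.csv -o overlap.csv
proxrange kinship --overlaps overlap.csv --n-perm 10000 --seed 1 -o contrast.json
```

which prints

```
wrote 44482 records from 65 stations to sim
13732 fixes from 44482 records (seed 1) → fixes.csv
estimated 6 UDs → uds
15 dyads at level 0.95 → overlap.csv
mean UDOI kin=1.311 non-kin=0.021 p=0.0656 → contrast.json
```

`uds/summary.csv` then holds one row per individual, e.g.

```
tag_id,n_fixes,model,tau_s,n_effective,area_ha_95,area_ha_50
ML3,3767,OU,1.32,3767.0,4.5425,1.245
ML5,1643,OU,0.59,1643.0,2.3975,0.485
```

Reading the numbers: each bat's home range (`area_ha_95`) and core area
(`area_ha_50`) are in hectares; the mother–daughter dyad overlaps far
more (mean UDOI 1.31 — shared concentration in the same cells) than the
13 non-related dyads (0.02), and the grouped permutation test puts that
difference at p ≈ 0.07 with only 15 dyads in the batch. The fitted OU
timescale is tiny here because the random band placement adds
independent noise to every fix, which the movement model reads as fast
decorrelation — see `docs/methods.md` for why that is expected and what
it implies.

The packaged reference table from the field accuracy experiment is
summarized with:

```sh
proxrange compare -o summary.json
# n=7: mean BA hr=0.88 core=0.78; paired t hr=1.92 → summary.json
```

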