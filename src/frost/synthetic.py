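"""Synthetic study generator for the freezing-resistance pipeline.

Emulates the structure of an alpine cryophilic-grassland study so that
every pipeline stage can be exercised end-to-end with known truth:

* leaf cooling thermograms — a 2 °C·h⁻¹ ramp from 0 to −19 °C sampled at
  1 Hz, with a latent-heat exotherm injected at each leaf's nucleation
  temperature (linear rise to the freezing point over ~30 s, exponential
  relaxation back to the ramp, time constant 120 s) plus Gaussian sensor
  noise;
* freezing damage assays — logistic photoinactivation in temperature,
  midpoint at the species' true LT50, sampled at the −5/−10/−15/−19 °C
  target grid plus 4 °C controls, five replicate leaves each;
* a species trait table — 42 species in four growth forms (8 cushions,
  8 graminoids, 23 forbs, 3 shrubs), graminoids the hardiest archetype,
  an LDMC–LT50 rank correlation induced by a Gaussian copula;
* a plot × species cover matrix — 38 plots spanning 1940–2428 m, species
  covers from Gaussian altitudinal niches whose optima rise as true LT50
  falls (hardier species peak higher), soft low-altitude species having
  the broader niches, plus an engineer species present everywhere at high
  cover.  This yields declining freezing-resistance CWMs and rising Rao
  FD with altitude.

All generators are deterministic given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import CommunityMatrix
from .errors import InputError
from .thermogram import ThermogramTrace

#: growth-form composition of the default species pool
DEFAULT_GROWTH_FORM_COUNTS: dict[str, int] = {
    "cushion": 8, "graminoid": 8, "forb": 23, "shrub": 3,
}

#: mechanism mix per growth form (FT, FA, FS fractions); overall ≈
#: 20 FT / 18 FA / 4 FS of 42 species
GF_MECHANISM_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "graminoid": (1.0, 0.0, 0.0),
    "cushion": (0.625, 0.375, 0.0),
    "forb": (6 / 23, 13 / 23, 4 / 23),
    "shrub": (1 / 3, 2 / 3, 0.0),
}

#: archetype NT means per growth form (°C)
GF_NT_MEAN_C: dict[str, float] = {
    "cushion": -6.8, "graminoid": -7.2, "forb": -6.4, "shrub": -6.6,
}

#: mean NT − LT50 gap for freezing-tolerant species per growth form (K);
#: graminoids carry the largest gap so their LT50 archetype sits ~6–7 K
#: below the other forms
GF_FT_GAP_K: dict[str, float] = {
    "graminoid": 6.5, "cushion": 4.0, "forb": 3.5, "shrub": 3.5,
}

ENGINEER_SPECIES = "Festuca_curvifolia"


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator parameters; the defaults define the study conditions."""

    n_species: int = 42
    n_plots: int = 38
    altitude_min_m: float = 1940.0
    altitude_max_m: float = 2428.0
    growth_form_counts: dict[str, int] | None = None
    replicates: int = 5

    # thermogram model
    cooling_rate_C_per_h: float = 2.0
    sample_hz: float = 1.0
    ramp_floor_C: float = -19.0
    hold_s: float = 600.0
    rise_time_s: float = 30.0
    decay_tau_s: float = 120.0
    trace_sigma_K: float = 0.05
    nt_replicate_sd_K: float = 0.8
    fp_replicate_sd_K: float = 0.3

    # damage model
    target_temps_C: tuple[float, ...] = (-5.0, -10.0, -15.0, -19.0)
    damage_slope_k: float = 1.5
    fv_fm_sigma: float = 0.03
    f_max: float = 0.8

    # trait couplings
    ldmc_lt50_spearman: float = -0.55
    lt50_optimum_coupling: float = 1.0  # 0 → no altitude sorting of hardiness

    # community niche model
    opt_jitter_m: float = 60.0
    niche_width_base_m: float = 60.0
    niche_width_soft_gain_m: float = 110.0
    cover_scale_pct: float = 40.0
    cover_threshold_pct: float = 1.0
    engineer: bool = True
    engineer_species: str = ENGINEER_SPECIES

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_plots < 3 or self.replicates < 1:
            raise InputError("scenario counts must be positive "
                             "(>= 2 species, >= 3 plots, >= 1 replicate)")
        if self.damage_slope_k <= 0:
            raise InputError("damage slope k must be positive")
        for name in ("trace_sigma_K", "fv_fm_sigma", "nt_replicate_sd_K",
                     "fp_replicate_sd_K"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def resolved_growth_forms(self) -> dict[str, int]:
        """Growth-form counts summing to n_species (proportional when the
        pool size differs from the default 42)."""
        if self.growth_form_counts is not None:
            counts = dict(self.growth_form_counts)
            if sum(counts.values()) != self.n_species:
                raise InputError("growth_form_counts must sum to n_species")
            return counts
        base = DEFAULT_GROWTH_FORM_COUNTS
        total = sum(base.values())
        counts = {gf: (c * self.n_species) // total for gf, c in base.items()}
        leftovers = self.n_species - sum(counts.values())
        for gf in sorted(base, key=lambda g: -base[g]):
            if leftovers <= 0:
                break
            counts[gf] += 1
            leftovers -= 1
        return {gf: n for gf, n in counts.items() if n > 0}


def _rng(scenario: SyntheticScenario, seed: int | None, stream: int):
    base = scenario.seed if seed is None else seed
    return np.random.default_rng([int(base), int(stream)])


def _quota(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder rounding of class fractions to integer counts."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    return counts


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------

def simulate_thermogram(nt_true: float, fp_true: float,
                        scenario: SyntheticScenario,
                        seed: int | None = None,
                        leaf_id: str = "L1",
                        species_id: str = "S1") -> ThermogramTrace:
    """One leaf cooling trace with an exotherm injected at ``nt_true``.

    The leaf follows the programmed ramp; when the ramp reaches
    ``nt_true`` the trace rises linearly to ``fp_true`` over
    ``rise_time_s``, then relaxes exponentially back toward the ramp.
    ``nt_true`` at or below the ramp floor yields a censored trace with
    no exotherm (a valid unfrozen-leaf outcome).
    """
    rate = scenario.cooling_rate_C_per_h / 3600.0  # K per second
    ramp_end = -scenario.ramp_floor_C / rate
    dt = 1.0 / scenario.sample_hz
    t = np.arange(0.0, ramp_end + scenario.hold_s, dt)
    ramp = np.maximum(scenario.ramp_floor_C, -rate * t)
    leaf = ramp.copy()

    if nt_true > scenario.ramp_floor_C:
        if not fp_true > nt_true:
            raise InputError("fp_true must exceed nt_true")
        t0 = -nt_true / rate
        t_peak = t0 + scenario.rise_time_s
        rising = (t > t0) & (t <= t_peak)
        leaf[rising] = nt_true + (fp_true - nt_true) * (t[rising] - t0) \
            / scenario.rise_time_s
        after = t > t_peak
        ramp_after = np.maximum(scenario.ramp_floor_C, -rate * t[after])
        excess_peak = fp_true - np.maximum(scenario.ramp_floor_C, -rate * t_peak)
        leaf[after] = ramp_after + excess_peak * np.exp(
            -(t[after] - t_peak) / scenario.decay_tau_s)

    if scenario.trace_sigma_K > 0:
        rng = _rng(scenario, seed, stream=1)
        leaf = leaf + rng.normal(0.0, scenario.trace_sigma_K, size=leaf.size)
    return ThermogramTrace.from_samples(leaf_id, species_id, t, leaf)


# ---------------------------------------------------------------------------
# damage assays
# ---------------------------------------------------------------------------

def logistic_phi(temp_C, lt50_true: float, k: float):
    """True photoinactivation fraction of the logistic damage model."""
    return 1.0 / (1.0 + np.exp(np.clip(k * (np.asarray(temp_C, dtype=float)
                                            - lt50_true), -500, 500)))


def simulate_damage_assay(lt50_true: float, k: float,
                          scenario: SyntheticScenario,
                          seed: int | None = None,
                          species_id: str = "S1") -> pd.DataFrame:
    """Tidy Fv/Fm records (species_id, leaf_id, treatment, fv_fm).

    Controls sit at the undamaged plateau ``f_max``; treated leaves at
    ``f_max · (1 − PhI_true(T))``; all values carry Gaussian noise and are
    clamped to [0, 1].
    """
    if k <= 0:
        raise InputError("damage slope k must be positive")
    rng = _rng(scenario, seed, stream=2)
    rows = []
    treatments = [None] + list(scenario.target_temps_C)
    for treatment in treatments:
        phi = 0.0 if treatment is None else float(
            logistic_phi(treatment, lt50_true, k))
        for rep in range(scenario.replicates):
            fv = scenario.f_max * (1.0 - phi)
            if scenario.fv_fm_sigma > 0:
                fv += rng.normal(0.0, scenario.fv_fm_sigma)
            label = "control" if treatment is None else format(treatment, "g")
            rows.append({
                "species_id": species_id,
                "leaf_id": f"{species_id}_{label}_r{rep + 1}",
                "treatment": label,
                "fv_fm": float(np.clip(fv, 0.0, 1.0)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species trait table
# ---------------------------------------------------------------------------

def simulate_trait_table(scenario: SyntheticScenario,
                         seed: int | None = None) -> pd.DataFrame:
    """Species pool with growth forms, mechanism archetypes, true NT/FP/
    LT50 and the four functional traits (Hmax, SLA, LDMC, seed mass).

    LT50 truths are derived from NT and a mechanism-dependent offset:
    tolerant species freeze-survive a growth-form-specific gap below NT
    (largest for graminoids), avoidant species are damaged at NT, and
    sensitive species already above it.  LDMC is rank-coupled to LT50
    through a Gaussian copula at the configured Spearman level.
    """
    rng = _rng(scenario, seed, stream=3)
    counts = scenario.resolved_growth_forms()
    rows = []
    idx = 0
    for gf in sorted(counts):
        n_gf = counts[gf]
        mech_counts = _quota(n_gf, GF_MECHANISM_FRACTIONS.get(
            gf, (0.45, 0.45, 0.10)))
        mechs = (["FT"] * mech_counts[0] + ["FA"] * mech_counts[1]
                 + ["FS"] * mech_counts[2])
        for mech in mechs:
            idx += 1
            nt_mean = GF_NT_MEAN_C.get(gf, -6.5)
            if mech == "FS":
                nt_mean -= 2.0  # sensitive species must nucleate colder
                                # than their (warm) damage temperature
            nt = float(np.clip(rng.normal(nt_mean, 1.2), -13.2, -5.3))
            if mech == "FT":
                gap = max(2.5, rng.normal(GF_FT_GAP_K.get(gf, 3.5), 1.0))
                lt50 = nt - gap
            elif mech == "FA":
                lt50 = nt + rng.normal(0.0, 0.2)
            else:
                lt50 = nt + max(1.2, rng.normal(2.0, 0.4))
            lt50 = float(np.clip(lt50, -18.4, -5.3))
            fp = float(np.clip(nt + max(0.8, rng.normal(3.5, 0.8)),
                               nt + 0.8, -0.7))
            rows.append({
                "species_id": f"sp{idx:02d}_{gf}",
                "growth_form": gf,
                "mechanism_true": mech,
                "nt_true_C": nt,
                "fp_true_C": fp,
                "lt50_true_C": lt50,
            })
    table = pd.DataFrame(rows)

    n = len(table)
    # Gaussian copula: convert the target Spearman into the latent Pearson
    rho_s = scenario.ldmc_lt50_spearman
    rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z_lt = sps.norm.ppf((sps.rankdata(table["lt50_true_C"]) - 0.5) / n)
    z = rho_g * z_lt + np.sqrt(max(0.0, 1.0 - rho_g ** 2)) * rng.normal(size=n)
    table["ldmc_mg_g"] = np.exp(5.5 + 0.35 * z)          # ~250 mg/g median
    table["hmax_cm"] = np.exp(rng.normal(2.0, 0.8, n))    # ~7 cm median
    table["sla_mm2_mg"] = np.exp(rng.normal(2.3, 0.4, n))
    table["seed_mass_mg"] = np.exp(rng.normal(-0.5, 1.2, n))
    return table


# ---------------------------------------------------------------------------
# community matrix
# ---------------------------------------------------------------------------

def simulate_community(scenario: SyntheticScenario,
                       trait_table: pd.DataFrame,
                       seed: int | None = None) -> CommunityMatrix:
    """Plot × species cover matrix from Gaussian altitudinal niches.

    Species niche optima track hardiness: with positive coupling, the
    lower a species' true LT50 the higher its optimum.  Soft (warm-LT50)
    species get the broader niches, so their tails reach the summit while
    narrow hardy specialists drop out downslope — high plots then mix
    hardy and soft species (high Rao FD, low CWM) and low plots hold soft
    species only.  An engineer species is present everywhere at high
    cover.  Every plot keeps at least two non-engineer species.
    """
    rng = _rng(scenario, seed, stream=4)
    alts = np.sort(rng.uniform(scenario.altitude_min_m,
                               scenario.altitude_max_m, scenario.n_plots))
    plot_ids = [f"plot{i + 1:02d}" for i in range(scenario.n_plots)]

    lt50 = trait_table["lt50_true_C"].to_numpy()
    span = np.ptp(lt50)
    hardiness = ((lt50.max() - lt50) / span if span > 0
                 else np.full(lt50.size, 0.5))
    c = scenario.lt50_optimum_coupling
    base = hardiness if c >= 0 else 1.0 - hardiness
    mix = abs(c) * base + (1.0 - abs(c)) * rng.uniform(size=lt50.size)
    alt_span = scenario.altitude_max_m - scenario.altitude_min_m
    opt = (scenario.altitude_min_m + mix * alt_span
           + rng.normal(0.0, scenario.opt_jitter_m, lt50.size))
    width = (scenario.niche_width_base_m
             + scenario.niche_width_soft_gain_m * (1.0 - hardiness))
    amplitude = np.exp(rng.normal(0.0, 0.4, lt50.size))

    raw = (scenario.cover_scale_pct * amplitude[None, :]
           * np.exp(-0.5 * ((alts[:, None] - opt[None, :])
                            / width[None, :]) ** 2))
    cover = np.where(raw >= scenario.cover_threshold_pct, raw, 0.0)
    # every plot keeps its two best-supported species, thresholded or not
    for i in range(cover.shape[0]):
        if (cover[i] > 0).sum() < 2:
            top = np.argsort(raw[i])[::-1][:2]
            cover[i, top] = np.maximum(raw[i, top], 0.5)

    frame = pd.DataFrame(cover, index=pd.Index(plot_ids, name="plot_id"),
                         columns=trait_table["species_id"].tolist())
    if scenario.engineer:
        frame[scenario.engineer_species] = rng.uniform(
            50.0, 80.0, scenario.n_plots)
    return CommunityMatrix(frame, pd.Series(alts, index=frame.index,
                                            name="altitude_m"))


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    scenario: SyntheticScenario
    trait_table: pd.DataFrame
    traces: list[ThermogramTrace] = field(repr=False)
    damage_records: pd.DataFrame = field(repr=False)
    community: CommunityMatrix = field(repr=False)


def simulate_dataset(scenario: SyntheticScenario,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate every pipeline input for one synthetic study.

    Replicate leaves draw their own nucleation and freezing-point values
    around the species truths; leaves whose replicate NT falls below the
    ramp floor produce censored (exotherm-free) traces.
    """
    base = scenario.seed if seed is None else seed
    table = simulate_trait_table(scenario, seed=base)
    rng = _rng(scenario, base, stream=5)
    traces: list[ThermogramTrace] = []
    damage_frames = []
    for row in table.itertuples():
        for rep in range(scenario.replicates):
            nt_r = row.nt_true_C + rng.normal(0.0, scenario.nt_replicate_sd_K)
            fp_r = row.fp_true_C + rng.normal(0.0, scenario.fp_replicate_sd_K)
            fp_r = min(-0.2, max(fp_r, nt_r + 0.5))
            traces.append(simulate_thermogram(
                nt_r, fp_r, scenario,
                seed=int(rng.integers(2 ** 31)),
                leaf_id=f"{row.species_id}_leaf{rep + 1}",
                species_id=row.species_id))
        damage_frames.append(simulate_damage_assay(
            row.lt50_true_C, scenario.damage_slope_k, scenario,
            seed=int(rng.integers(2 ** 31)), species_id=row.species_id))
    community = simulate_community(scenario, table, seed=base)
    return SimulatedDataset(scenario, table, traces,
                            pd.concat(damage_frames, ignore_index=True),
                            community)


def traces_to_frame(traces: list[ThermogramTrace]) -> pd.DataFrame:
    """Long-format trace table (species_id, leaf_id, time_s, temp_C)."""
    parts = [pd.DataFrame({
        "species_id": tr.species_id, "leaf_id": tr.leaf_id,
        "time_s": tr.time_s, "temp_C": tr.temp_C}) for tr in traces]
    return pd.concat(parts, ignore_index=True)
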