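"""Synthetic whole-blood miRNA cohorts with planted, recorded ground truth.

The generator emulates the statistical structure the analysis stages
assume: log-scale intensities with a long-tailed baseline (a few dominant
miRNAs), linear and quadratic/logistic age trends calibrated to a target
Spearman coefficient, sex offsets, age-dependent disease effects, 5'/3'
arm pairs with or without an age drift of arm usage, plasma proteins
negatively coupled to the most-decreasing miRNAs, interaction tables with
decoys, and blood-compound presence with class-dependent bias.  Every
planted fact is recorded in a :class:`TruthLedger`.

All randomness flows from a single integer seed; child seeds for the
sub-generators are derived deterministically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InteractionTable, SampleMetadata
from .stats import spearman_vs_vector

MIRNA_CLASSES = (
    "age_up_linear", "age_down_linear", "age_nonlinear_up",
    "age_nonlinear_down", "sex_only", "disease_only", "null",
)

#: cohort composition of the study the generator emulates
DEFAULT_GROUP_PROPS = {
    "HC": 1334 / 4393, "PD": 944 / 4393, "HD": 607 / 4393,
    "NTLD": 586 / 4393, "LC": 517 / 4393, "OD": 405 / 4393,
}

#: planted class proportions: ~20% up / 20% down with age, a small
#: nonlinear contingent skewed toward decreasing trajectories
DEFAULT_FRACTIONS = {
    "age_up_linear": 0.20, "age_down_linear": 0.20,
    "age_nonlinear_up": 0.01, "age_nonlinear_down": 0.035,
    "sex_only": 0.05, "disease_only": 0.05,
}

DEFAULT_EFFECT_SIZES = {
    "age_sc": 0.3,           # mean target |Spearman| of linear age classes
    "age_sc_spread": 0.1,    # per-miRNA target drawn uniformly +- this,
                             # giving the continuous SC spectrum of real data
    "nonlinear_sc": 0.2,     # mean linear tilt of nonlinear classes: they
                             # are altered with age (solidly significant)
                             # while dc exceeds what the tilt predicts
    "nonlinear_sc_spread": 0.05,
    "nonlinear_curve": 2.5,  # curvature amplitude, units of noise_sd
    "sex_d": 0.6,            # Cohen's d of sex_only miRNAs
    "disease_d": 0.8,        # Cohen's d of disease_only miRNAs at age 30
    "disease_decay": 0.8,    # fraction of d lost across the age range
}

COMPOUNDS = ("serum", "microvesicles", "RBC", "CD15", "CD19",
             "CD8", "CD56", "CD4", "CD14", "CF")


@dataclass
class TruthLedger:
    """Planted ground truth of one synthetic dataset."""

    mirna_class: dict[str, str] = field(default_factory=dict)
    disease_group: dict[str, str] = field(default_factory=dict)
    arm_switch: dict[str, dict] = field(default_factory=dict)
    protein_trend: dict[str, str] = field(default_factory=dict)
    true_regulations: list[tuple[str, str]] = field(default_factory=list)

    def mirnas_of_class(self, cls: str) -> list[str]:
        return [m for m, c in self.mirna_class.items() if c == cls]

    def to_dict(self) -> dict:
        return {
            "mirna_class": self.mirna_class,
            "disease_group": self.disease_group,
            "arm_switch": self.arm_switch,
            "protein_trend": self.protein_trend,
            "true_regulations": [list(t) for t in self.true_regulations],
        }


def child_seed(seed: int, stream: str) -> int:
    """Deterministic per-component child seed below 2^31."""
    tag = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def _slope_for_sc(target_sc: float, noise_sd: float, age_sd: float) -> float:
    """Linear slope yielding approximately the target Spearman coefficient.

    Uses the bivariate-normal relation r = 2 sin(pi * rho_s / 6) between
    Pearson and Spearman correlation; for uniform ages with Gaussian noise
    the mapping is accurate to within the stated +-0.05 tolerance.
    """
    r = 2.0 * np.sin(np.pi * target_sc / 6.0)
    r = float(np.clip(r, -0.999, 0.999))
    return noise_sd * r / (age_sd * np.sqrt(1.0 - r * r))


def simulate_cohort(
    n_samples: int = 800,
    n_mirnas: int = 1000,
    fractions: dict | None = None,
    effect_sizes: dict | None = None,
    noise_sd: float = 1.0,
    age_range: tuple[int, int] = (30, 79),
    group_props: dict | None = None,
    seed: int = 0,
    nonlinear_shape: str = "quadratic",
) -> tuple[ExpressionMatrix, SampleMetadata, TruthLedger]:
    """Generate a cohort matrix, metadata and the truth ledger.

    Ages are uniform integers on ``age_range``; the per-miRNA baseline is
    long-tailed (gamma on the log2 scale).  Disease effects follow a
    linearly decaying Cohen's d profile by default (U-shaped for PD, which
    clinically peaks late).
    """
    if n_samples < 40:
        raise ValueError("need n_samples >= 40")
    lo, hi = age_range
    if hi <= lo:
        raise ValueError("degenerate age range")
    fractions = {**DEFAULT_FRACTIONS, **(fractions or {})}
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("class fractions sum to more than 1")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("negative class fraction")
    effect = {**DEFAULT_EFFECT_SIZES, **(effect_sizes or {})}
    group_props = group_props or DEFAULT_GROUP_PROPS

    rng = np.random.default_rng(child_seed(seed, "cohort"))
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    ages = rng.integers(lo, hi + 1, size=n_samples)
    sexes = rng.choice(["male", "female"], size=n_samples)
    groups = rng.choice(list(group_props), size=n_samples,
                        p=np.array(list(group_props.values()))
                        / sum(group_props.values()))
    meta = SampleMetadata(pd.DataFrame(
        {"age": ages, "sex": sexes, "group": groups},
        index=pd.Index(sample_ids, name="sample_id")), (lo, hi))

    mirna_ids = [f"mir-{i:04d}" for i in range(n_mirnas)]
    classes = _assign_classes(n_mirnas, fractions, rng)
    truth = TruthLedger(mirna_class=dict(zip(mirna_ids, classes)))

    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    age_sd = float(np.std(np.arange(lo, hi + 1)))
    u = (ages - mid) / half  # in [-1, 1]
    curve_amp = effect["nonlinear_curve"] * noise_sd
    # quadratic and logistic shapes orthogonalized against age within the
    # sampled cohort, so the planted linear component is exactly the tilt
    # (an asymmetric age draw would otherwise leak curvature into SC)
    def _orth(shape: np.ndarray) -> np.ndarray:
        a_c = ages - ages.mean()
        shape = shape - shape.mean()
        return shape - (float(shape @ a_c) / float(a_c @ a_c)) * a_c

    quad = _orth(u**2)
    logi = _orth(1.0 / (1.0 + np.exp(-6.0 * u)))
    # the curvature dilutes rank correlation like extra noise; widen the
    # noise scale used for the tilt calibration accordingly
    tilt_noise = float(np.sqrt(noise_sd**2 + (curve_amp * quad.std()) ** 2))
    is_male = (sexes == "male").astype(float)
    disease_cycle = ("PD", "HD", "NTLD", "LC")

    baseline = 2.0 + rng.gamma(shape=1.5, scale=2.0, size=n_mirnas)
    values = np.empty((n_mirnas, n_samples))
    n_disease = 0
    for i, cls in enumerate(classes):
        signal = np.zeros(n_samples)
        if cls in ("age_up_linear", "age_down_linear"):
            target = effect["age_sc"] + rng.uniform(-1, 1) * effect["age_sc_spread"]
            slope = _slope_for_sc(target, noise_sd, age_sd)
            sign = 1.0 if cls == "age_up_linear" else -1.0
            signal = sign * slope * (ages - mid)
        elif cls in ("age_nonlinear_up", "age_nonlinear_down"):
            sign = 1.0 if cls == "age_nonlinear_up" else -1.0
            target = effect["nonlinear_sc"] \
                + rng.uniform(-1, 1) * effect["nonlinear_sc_spread"]
            tilt = _slope_for_sc(target, tilt_noise, age_sd)
            shape = logi if nonlinear_shape == "logistic" else quad
            signal = sign * (tilt * (ages - mid) + curve_amp * shape)
        elif cls == "sex_only":
            signal = effect["sex_d"] * noise_sd * (is_male - 0.5)
        elif cls == "disease_only":
            grp = disease_cycle[n_disease % len(disease_cycle)]
            n_disease += 1
            truth.disease_group[mirna_ids[i]] = grp
            d_age = _disease_profile(ages, grp, effect, (lo, hi))
            signal = d_age * noise_sd * (groups == grp).astype(float)
        values[i] = baseline[i] + signal + rng.normal(0.0, noise_sd, n_samples)

    expr = ExpressionMatrix(pd.DataFrame(
        values, index=pd.Index(mirna_ids, name="feature_id"), columns=sample_ids))
    return expr, meta, truth


def _assign_classes(n: int, fractions: dict, rng: np.random.Generator) -> list[str]:
    counts = {cls: int(round(f * n)) for cls, f in fractions.items()}
    while sum(counts.values()) > n:
        biggest = max(counts, key=counts.get)
        counts[biggest] -= 1
    classes = []
    for cls, c in counts.items():
        classes.extend([cls] * c)
    classes.extend(["null"] * (n - len(classes)))
    rng.shuffle(classes)
    return classes


def _disease_profile(ages: np.ndarray, group: str, effect: dict,
                     age_range: tuple[int, int]) -> np.ndarray:
    """Cohen's d of the disease offset as a function of age.

    Default: linear decay from ``disease_d`` at the young end, losing
    ``disease_decay`` of it across the range.  Parkinson's disease is
    U-shaped (effects re-emerge in the old), echoing its late clinical
    dynamics.
    """
    lo, hi = age_range
    t = (ages - lo) / (hi - lo)
    d0 = effect["disease_d"]
    if group == "PD":
        return d0 * (1.0 - effect["disease_decay"] * (1.0 - (2.0 * t - 1.0) ** 2))
    return d0 * (1.0 - effect["disease_decay"] * t)


def simulate_arm_pairs(
    n_pairs: int,
    n_switch: int,
    switch_magnitude: float,
    samples: SampleMetadata,
    seed: int = 0,
    frac_noise: float = 0.05,
    total_sd: float = 0.3,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthLedger]:
    """Arm-level expression for precursor pairs, some with an age drift of
    5' usage.

    Switched pairs have the mean 5' fraction drifting monotonically by
    ``switch_magnitude`` across the age range (direction alternating), so
    the per-arm age correlations have opposite signs; other pairs keep an
    age-constant fraction.  Values are log2 intensities.
    """
    if n_switch > n_pairs:
        raise ValueError("n_switch cannot exceed n_pairs")
    if not (0.0 < switch_magnitude < 1.0):
        raise ValueError("switch_magnitude must be in (0, 1)")
    rng = np.random.default_rng(child_seed(seed, "arm_pairs"))
    ages = samples.ages.to_numpy(dtype=float)
    lo, hi = samples.age_range
    t = (ages - lo) / (hi - lo)
    n_samples = len(samples.sample_ids)

    rows = []
    arm_ids = []
    pair_rows = []
    truth = TruthLedger()
    switch_flags = np.zeros(n_pairs, dtype=bool)
    switch_flags[:n_switch] = True
    rng.shuffle(switch_flags)
    for j in range(n_pairs):
        pid = f"pre-{j:03d}"
        id5, id3 = f"{pid}-5p", f"{pid}-3p"
        if switch_flags[j]:
            to_5p = bool(rng.integers(0, 2))
            f0 = rng.uniform(0.15, 0.8 - switch_magnitude)
            mean_frac = f0 + switch_magnitude * (t if to_5p else 1.0 - t)
            truth.arm_switch[pid] = {"switch": True,
                                     "direction": "to_5p" if to_5p else "to_3p"}
        else:
            mean_frac = np.full(n_samples, rng.uniform(0.2, 0.8))
            truth.arm_switch[pid] = {"switch": False, "direction": None}
        frac = np.clip(mean_frac + rng.normal(0.0, frac_noise, n_samples),
                       0.01, 0.99)
        total_log2 = rng.uniform(6.0, 12.0) + rng.normal(0.0, total_sd, n_samples)
        total = 2.0**total_log2
        rows.append(np.log2(total * frac))
        arm_ids.append(id5)
        rows.append(np.log2(total * (1.0 - frac)))
        arm_ids.append(id3)
        pair_rows.append({"precursor": pid, "mirna_5p": id5, "mirna_3p": id3})

    expr = ExpressionMatrix(pd.DataFrame(
        np.array(rows), index=pd.Index(arm_ids, name="feature_id"),
        columns=samples.sample_ids))
    return expr, pd.DataFrame(pair_rows), truth


def simulate_proteins_and_interactions(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    truth: TruthLedger,
    n_proteins: int = 500,
    n_true_regulations: int = 36,
    coupling: float = -1.0,
    decoy_count: int = 300,
    seed: int = 0,
    hub_size: int = 9,
    protein_noise: float = 0.3,
) -> tuple[ExpressionMatrix, InteractionTable, TruthLedger]:
    """Plasma proteins (log10 RFU) plus an interaction table with decoys.

    True regulations wire the empirically most-decreasing planted age-down
    miRNAs to hub proteins whose age trend is ``-coupling`` times a unit
    upward trend (so ``coupling = 0`` severs the trajectory correlation and
    the downstream core network collapses).  Each hub protein receives
    ``hub_size`` (>= 9) targeting miRNAs so the targeting filter is
    satisfiable.  Decoy rows carry strong evidence but wire uncorrelated
    (flat) proteins, plus weak/predicted-evidence noise rows.
    """
    if coupling > 0:
        raise ValueError("coupling must be <= 0 (repressive miRNA->protein)")
    if hub_size < 9:
        raise ValueError("hub_size must be >= 9 for the targeting filter")
    rng = np.random.default_rng(child_seed(seed, "proteins"))
    meta = meta.aligned_to(expr)
    ages = meta.ages.to_numpy(dtype=float)
    lo, hi = meta.age_range
    mid = (lo + hi) / 2.0
    age_sd = float(np.std(np.arange(lo, hi + 1)))

    down = truth.mirnas_of_class("age_down_linear")
    n_hubs = int(np.ceil(n_true_regulations / hub_size))
    n_true_mirnas = min(n_true_regulations, len(down))
    if n_true_mirnas < hub_size:
        raise ValueError("not enough planted age-down miRNAs for one hub")
    # the most decreasing planted miRNAs, so the bottom-quantile selection
    # downstream recovers exactly these candidates
    sub = expr.subset_features(down)
    sc, _ = spearman_vs_vector(sub.values.to_numpy(dtype=float), ages)
    order = np.argsort(sc, kind="mergesort")
    true_mirnas = [down[i] for i in order[:n_true_mirnas]]

    protein_ids = [f"PROT{i:04d}" for i in range(n_proteins)]
    if n_hubs > n_proteins:
        raise ValueError("more hubs than proteins")
    trend = np.array(["flat"] * n_proteins, dtype=object)
    trend[:n_hubs] = "hub_up"
    n_mild = int(0.2 * n_proteins)
    trend[n_hubs:n_hubs + n_mild] = "mild_up"
    trend[n_hubs + n_mild:n_hubs + 2 * n_mild] = "down"

    hub_r = min(0.9, 0.5 * abs(coupling))
    r_to_slope = lambda r: protein_noise * r / (age_sd * np.sqrt(1 - r * r)) if r > 0 else 0.0
    slopes = {"hub_up": r_to_slope(hub_r), "mild_up": r_to_slope(0.25),
              "down": -r_to_slope(0.25), "flat": 0.0}
    values = np.empty((n_proteins, len(ages)))
    ledger = TruthLedger()
    for i, pid in enumerate(protein_ids):
        base = rng.uniform(2.5, 4.5)
        values[i] = base + slopes[str(trend[i])] * (ages - mid) \
            + rng.normal(0.0, protein_noise, len(ages))
        ledger.protein_trend[pid] = str(trend[i])
    proteins = ExpressionMatrix(pd.DataFrame(
        values, index=pd.Index(protein_ids, name="feature_id"),
        columns=list(meta.sample_ids)))

    inter_rows = []
    seen = set()

    def add(m, g, ev):
        key = (m, g, ev)
        if key not in seen:
            seen.add(key)
            inter_rows.append({"mirna_id": m, "gene_id": g, "evidence": ev})

    for h in range(n_hubs):
        hub = protein_ids[h]
        for w in range(hub_size):
            m = true_mirnas[(h * hub_size + w) % n_true_mirnas]
            add(m, hub, "strong")
            ledger.true_regulations.append((m, hub))
    flat_ids = [p for p, t in zip(protein_ids, trend) if t == "flat"]
    all_mirnas = expr.feature_ids
    for _ in range(decoy_count):
        add(all_mirnas[rng.integers(len(all_mirnas))],
            flat_ids[rng.integers(len(flat_ids))], "strong")
    for _ in range(decoy_count):
        add(all_mirnas[rng.integers(len(all_mirnas))],
            protein_ids[rng.integers(n_proteins)],
            "weak" if rng.integers(2) else "predicted")
    interactions = InteractionTable(pd.DataFrame(inter_rows))
    return proteins, interactions, ledger


DEFAULT_CLASS_BIAS = {
    # age-increasing miRNAs lean toward B cells and serum; decreasing ones
    # toward neutrophils and red blood cells
    "age_up_linear": {"CD19": 2.0, "serum": 2.0},
    "age_nonlinear_up": {"CD19": 2.0, "serum": 2.0},
    "age_down_linear": {"CD15": 2.0, "RBC": 2.0},
    "age_nonlinear_down": {"CD15": 2.0, "RBC": 2.0},
}


def simulate_compound_presence(
    feature_ids,
    truth: TruthLedger,
    compounds=COMPOUNDS,
    class_bias: dict | None = None,
    base_rate: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Boolean miRNA x compound presence with per-class compound bias.

    Presence is Bernoulli(base_rate * multiplier) with the multiplier from
    ``class_bias`` keyed by the miRNA's planted class (probabilities capped
    at 0.95).  A miRNA absent from every compound is allowed.
    """
    compounds = list(compounds)
    if len(set(compounds)) != len(compounds):
        raise ValueError("compound labels must be unique")
    if class_bias is None:
        class_bias = DEFAULT_CLASS_BIAS
    rng = np.random.default_rng(child_seed(seed, "presence"))
    probs = np.full((len(feature_ids), len(compounds)), base_rate)
    for i, fid in enumerate(feature_ids):
        cls = truth.mirna_class.get(fid, "null")
        for comp, mult in class_bias.get(cls, {}).items():
            if comp in compounds:
                probs[i, compounds.index(comp)] = min(0.95, base_rate * mult)
    presence = rng.random(probs.shape) < probs
    return pd.DataFrame(presence, index=pd.Index(list(feature_ids), name="feature_id"),
                        columns=compounds)
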