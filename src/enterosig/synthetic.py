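"""Seeded synthetic study generator.

Emulates the inputs of a three-arm diet-intervention study — a control diet
(ND), a high-fat diet (HFD) and the high-fat diet with the treatment
(HFD-T070) — so that every downstream stage of the pipeline can be tested
without animal data:

* an overdispersed compositional count table (taxa x samples) with
  per-taxon effect patterns planted from the six-model bank,
* a per-animal phenotype (e.g. total cholesterol, g/L) linearly coupled to
  designated taxa,
* post-gavage triglyceride curves (rise-and-return) and post-Poloxamer
  linear TG rises,
* paired dual-isotope dose/serum scintillation counts,
* an RT-qPCR Ct table.

Counts are drawn by closing log-normal taxon weights to proportions and
sampling a multinomial at a Poisson-varying depth; a planted taxon's weight
is multiplied, per group, by its model's coded unit (normalised to unit
mean) and by the effect-size multiplier, so its expected relative abundance
across groups is proportional to the coded units.  All randomness flows
from one integer seed per spec through a local generator.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .indicators import PatternBank, default_bank
from .physiology import IsotopeRecord, KineticsSeries
from .tables import AbundanceTable

DEFAULT_GROUPS = ("ND", "HFD", "HFD-T070")

#: Phylum pool and sampling weights for the default synthetic taxonomy,
#: loosely shaped like a rodent cecal community.
PHYLUM_WEIGHTS = {
    "Firmicutes": 0.40,
    "Bacteroidetes": 0.30,
    "Proteobacteria": 0.12,
    "Actinobacteria": 0.08,
    "Verrucomicrobia": 0.05,
    "Deferribacteres": 0.03,
    "Campylobacterota": 0.02,
}


def _spec_hash(spec) -> str:
    payload = repr(sorted(asdict(spec).items(), key=lambda kv: kv[0]))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def provenance_header(spec) -> str:
    return f"enterosig synthetic spec={type(spec).__name__}:{_spec_hash(spec)} seed={spec.seed}"


# ---------------------------------------------------------------------------
# Specs


@dataclass
class CommunitySpec:
    """Design of a synthetic three-group community count table.

    `planted` lists (taxon index, model id, effect multiplier) triples.
    The model's coded units set the taxon's expected abundance profile
    across groups and the effect multiplier sets the realized fold change
    of the coded 3-fold control->disease contrast: at effect 3 the expected
    group relative abundances are exactly proportional to the coded units,
    larger effects amplify the pattern, effect -> 1 flattens it.
    `dispersion` is the log-sd of per-sample multiplicative noise on taxon
    weights; `baseline_sigma` the log-sd of between-taxon baseline sizes.
    `baseline_overrides` pins chosen taxa to fixed baseline weights (on the
    scale where the typical taxon is ~1), e.g. to plant effects on
    moderately abundant rather than randomly sized taxa.
    """

    n_taxa: int
    n_per_group: int = 16
    groups: tuple[str, ...] = DEFAULT_GROUPS
    depth_mean: float = 20_000.0
    dispersion: float = 0.3
    baseline_sigma: float = 1.5
    planted: tuple[tuple[int, int, float], ...] = ()
    taxonomy_map: dict | None = None
    baseline_overrides: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        if self.n_per_group < 3:
            raise ValueError("group sizes must be at least 3")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dispersion < 0 or self.baseline_sigma < 0:
            raise ValueError("dispersion parameters must be non-negative")
        valid_ids = {m.model_id for m in default_bank(self.groups).models}
        for taxon, model_id, effect in self.planted:
            if not (0 <= taxon < self.n_taxa):
                raise ValueError(f"planted taxon index {taxon} out of range")
            if model_id not in valid_ids:
                raise ValueError(
                    f"taxon {taxon}: invalid model id {model_id} "
                    f"(expected one of {sorted(valid_ids)})"
                )
            if effect <= 0:
                raise ValueError(f"taxon {taxon}: effect multiplier must be > 0")


@dataclass
class PhenotypeSpec:
    """Per-animal phenotype coupled linearly to designated taxa.

    phenotype_s = base + sum_t w_t * z_t(s) + N(0, noise_sd), with z_t the
    standardized relative abundance of taxon t across samples.
    """

    base_level: float = 2.0          # g/L, plausible hamster total cholesterol
    coupled_taxa: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class KineticsSpec:
    """Synthetic kinetics assay: post-gavage TG ('oftt') or Poloxamer rise.

    `group_params` maps group -> parameter dict.  For ``oftt``: baseline
    (mg/mL), amplitude (peak rise, mg/mL), tpeak (min).  For ``poloxamer``:
    baseline and slope (mg/mL/min).
    """

    assay: str
    timepoints: tuple[float, ...]
    group_params: dict
    n_animals: int = 13
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("oftt", "poloxamer"):
            raise ValueError(f"unknown assay {self.assay!r}")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must start at 0 and strictly increase")
        for g, p in self.group_params.items():
            if self.assay == "poloxamer" and p.get("slope", 0.0) < 0:
                raise ValueError(f"group {g}: Poloxamer slope must be non-negative")
            if self.assay == "oftt" and p.get("amplitude", 0.0) < 0:
                raise ValueError(f"group {g}: OFTT amplitude must be non-negative")


#: Post-gavage sampling grid (min) of the oral fat tolerance test.
OFTT_TIMEPOINTS = (0.0, 150.0, 330.0, 510.0, 720.0)
#: Post-injection sampling grid (min) of the Poloxamer secretion assay.
POLOXAMER_TIMEPOINTS = (0.0, 45.0, 90.0, 120.0)


@dataclass
class StudyDesign:
    """Sample -> group/cage map plus the bank of pattern codings."""

    metadata: pd.DataFrame            # columns: sample, group, cage
    bank: PatternBank
    groups: tuple[str, ...] = DEFAULT_GROUPS

    def group_series(self) -> pd.Series:
        return self.metadata.set_index("sample")["group"]


# ---------------------------------------------------------------------------
# Generators


def _default_taxonomy(n_taxa: int, rng: np.random.Generator) -> dict:
    phyla = list(PHYLUM_WEIGHTS)
    probs = np.array(list(PHYLUM_WEIGHTS.values()))
    choice = rng.choice(len(phyla), size=n_taxa, p=probs / probs.sum())
    return {
        t: (phyla[choice[t]], f"Genus{t:03d}") for t in range(n_taxa)
    }


def generate_community(spec: CommunitySpec) -> tuple[AbundanceTable, StudyDesign]:
    """Draw a seeded synthetic count table and its study design.

    Counts per sample are multinomial at Poisson(depth_mean) depth on
    closed log-normal taxon weights; planted taxa carry their model's
    coded-unit profile across groups, scaled by the effect multiplier.
    """
    rng = np.random.default_rng(spec.seed)
    bank = default_bank(spec.groups)
    n_groups = len(spec.groups)

    taxonomy = spec.taxonomy_map or _default_taxonomy(spec.n_taxa, rng)
    baseline = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=spec.n_taxa)
    for taxon, weight in (spec.baseline_overrides or {}).items():
        if not (0 <= taxon < spec.n_taxa) or weight <= 0:
            raise ValueError(f"invalid baseline override for taxon {taxon}")
        baseline[taxon] = weight
    q = baseline / baseline.sum()  # baseline community proportions

    # Every model in the bank carries a 3-fold control->disease contrast
    # (units 25 -> 75), so the effect multiplier is calibrated as the
    # realized fold change of that contrast: a planted taxon's expected
    # group profile is r_g = (u_g / u_control)^(ln e / ln 3).  At e = 3 the
    # profile reproduces the coded units exactly; larger e amplifies the
    # pattern, e -> 1 flattens it, and the power map preserves the unit
    # ratios' ordering so the planted model stays identifiable throughout.
    # The remaining probability mass is renormalized across the unplanted
    # taxa so closure does not distort planted patterns.
    planted_idx = np.array([t for t, _, _ in spec.planted], dtype=int)
    weights = np.tile(q[:, None], (1, n_groups))  # taxa x groups, columns sum to 1
    if planted_idx.size:
        for taxon, model_id, effect in spec.planted:
            units = np.asarray(bank.by_id(model_id).units, dtype=float)
            power = np.log(effect) / np.log(3.0)
            profile = (units / units[0]) ** power
            weights[taxon, :] = q[taxon] * profile / profile.mean()
        planted_mass = weights[planted_idx, :].sum(axis=0)
        if (planted_mass >= 0.9).any():
            raise ValueError(
                "planted taxa claim >= 90% of the community in some group; "
                "lower the effect multipliers or plant fewer/rarer taxa"
            )
        unplanted = np.setdiff1d(np.arange(spec.n_taxa), planted_idx)
        scale = (1.0 - planted_mass) / q[unplanted].sum()
        weights[unplanted, :] = q[unplanted, None] * scale[None, :]

    samples, labels, cages = [], [], []
    counts = np.zeros((spec.n_taxa, n_groups * spec.n_per_group), dtype=np.int64)
    col = 0
    for g_idx, group in enumerate(spec.groups):
        for a in range(spec.n_per_group):
            sample = f"{group}_{a + 1:02d}"
            samples.append(sample)
            labels.append(group)
            cages.append(f"{group}_c{a // 3 + 1}")  # 3 animals per cage
            w = weights[:, g_idx]
            if spec.dispersion > 0:
                w = w * rng.lognormal(0.0, spec.dispersion, size=spec.n_taxa)
            p = w / w.sum()
            depth = max(int(rng.poisson(spec.depth_mean)), 1)
            counts[:, col] = rng.multinomial(depth, p)
            col += 1

    taxa = [f"T{t:03d}" for t in range(spec.n_taxa)]
    lineages = pd.Series(
        {
            taxa[t]: f"k__Bacteria;p__{taxonomy[t][0]};g__{taxonomy[t][1]}"
            for t in range(spec.n_taxa)
        }
    )
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=taxa, columns=samples),
        lineages=lineages,
        level="otu",
    )
    design = StudyDesign(
        metadata=pd.DataFrame({"sample": samples, "group": labels, "cage": cages}),
        bank=bank,
        groups=spec.groups,
    )
    return table, design


def generate_phenotype(
    table: AbundanceTable, design: StudyDesign, spec: PhenotypeSpec
) -> pd.Series:
    """Phenotype vector linearly coupled to standardized taxon abundances."""
    rng = np.random.default_rng(spec.seed)
    rel = table.relative_abundance()
    values = np.full(len(table.samples), float(spec.base_level))
    for taxon_idx, weight in spec.coupled_taxa:
        if not (0 <= taxon_idx < rel.shape[0]):
            raise ValueError(f"unknown coupled taxon index {taxon_idx}")
        x = rel.iloc[taxon_idx].to_numpy()
        sd = x.std()
        if sd == 0:
            warnings.warn(
                f"coupled taxon {taxon_idx} has constant abundance; "
                "contributes nothing",
                stacklevel=2,
            )
            continue
        values = values + weight * (x - x.mean()) / sd
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.size)
    return pd.Series(values, index=table.samples, name="phenotype")


def _oftt_curve(t: np.ndarray, baseline: float, amplitude: float, tpeak: float) -> np.ndarray:
    # gamma-shaped rise-and-return: peaks at tpeak with height `amplitude`
    return baseline + amplitude * (t / tpeak) * np.exp(1.0 - t / tpeak)


def generate_kinetics(spec: KineticsSpec) -> list[KineticsSeries]:
    """Seeded per-animal kinetics curves for the OFTT or Poloxamer assay."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    series = []
    for group, params in spec.group_params.items():
        for a in range(spec.n_animals):
            if spec.assay == "oftt":
                c = _oftt_curve(
                    t,
                    params.get("baseline", 1.0),
                    params.get("amplitude", 0.0),
                    params.get("tpeak", 300.0),
                )
            else:
                c = params.get("baseline", 1.0) + params.get("slope", 0.0) * t
            if spec.noise_sd > 0:
                c = c + rng.normal(0.0, spec.noise_sd, size=t.size)
                neg = c < 0
                if neg.any():
                    warnings.warn(
                        "noise drove concentrations negative; clipped at 0",
                        stacklevel=2,
                    )
                    c = np.clip(c, 0.0, None)
            series.append(
                KineticsSeries(
                    animal=f"{group}_{a + 1:02d}", group=group, times=t,
                    concentrations=c,
                )
            )
    return series


def generate_isotope_records(
    n: int,
    true_absorption,
    seed: int = 0,
    noise_sd: float = 0.0,
    dose_oral: float = 1.0e6,
    dose_iv: float = 2.5e6,
    iv_plasma_fraction: float = 0.05,
) -> list[IsotopeRecord]:
    """Paired dual-isotope dose/serum counts with a planted absorption truth.

    Per animal the IV-tracer plasma fraction is drawn log-normally around
    `iv_plasma_fraction`; the oral-tracer fraction is set so that the
    plasma-ratio estimator recovers `true_absorption` (%) in expectation
    (multiplicative log-normal noise with mean 1 when `noise_sd` > 0).
    `true_absorption` may be a scalar or one value per animal.
    """
    if dose_oral <= 0 or dose_iv <= 0:
        raise ValueError("dose counts must be positive")
    truth = np.broadcast_to(np.asarray(true_absorption, dtype=float), (n,))
    if ((truth <= 0) | (truth > 150)).any():
        raise ValueError("true absorption must lie in (0, 150] percent")
    rng = np.random.default_rng(seed)
    records = []
    for a in range(n):
        f_iv = iv_plasma_fraction * rng.lognormal(0.0, 0.2)
        ratio = truth[a] / 100.0
        if noise_sd > 0:
            ratio *= rng.lognormal(-0.5 * noise_sd**2, noise_sd)  # mean-one noise
        records.append(
            IsotopeRecord(
                animal=f"A{a + 1:03d}",
                dose_oral=dose_oral,
                dose_iv=dose_iv,
                serum_oral=dose_oral * f_iv * ratio,
                serum_iv=dose_iv * f_iv,
            )
        )
    return records


def generate_ct_table(
    groups: dict[str, int],
    control_group: str,
    log2_fold: dict[str, float],
    ct_reference: float = 20.0,
    ct_target_control: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic RT-qPCR Ct table with planted per-group expression changes.

    A group with log2 fold change ``f`` versus control gets target Ct values
    shifted by ``-f`` (one PCR cycle per doubling), so downstream 2^-ddCt
    recovers 2^f in expectation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in groups.items():
        shift = -log2_fold.get(group, 0.0)
        for a in range(n):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": f"{group}_{a + 1:02d}",
                    "group": group,
                    "ct_target": ct_target_control + shift + noise,
                    "ct_reference": ct_reference,
                }
            )
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not among groups")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The default synthetic study


def default_study(seed: int = 0) -> dict:
    """The package's reference synthetic study: 3 groups x 16 animals x 200 genera.

    Twelve taxa are planted, two per model of the default bank, with effect
    multiplier 3; the pairs on treatment-lowering models (1, 2, 6) are
    assigned to Firmicutes and the pair on the treatment-raising model (5)
    to Bacteroidetes, so the treated arm shows a falling
    Firmicutes/Bacteroidetes ratio.  Total cholesterol (g/L) is
    coupled positively to one model-2 taxon and negatively to one model-1
    taxon, with 0.15 g/L residual noise.  Kinetics, isotope and Ct inputs
    use group parameters in which the treated arm sits between the control
    and disease arms.
    """
    rng = np.random.default_rng(seed)
    n_taxa = 200
    taxonomy = _default_taxonomy(n_taxa, np.random.default_rng(seed + 17))
    planted = []
    planted_phyla = {
        1: "Firmicutes",
        2: "Firmicutes",
        5: "Bacteroidetes",
        6: "Firmicutes",
    }
    idx = 0
    for model_id in range(1, 7):
        for _ in range(2):
            planted.append((idx, model_id, 3.0))
            if model_id in planted_phyla:
                taxonomy[idx] = (planted_phyla[model_id], f"Genus{idx:03d}")
            idx += 1

    cspec = CommunitySpec(
        n_taxa=n_taxa,
        n_per_group=16,
        planted=tuple(planted),
        taxonomy_map=taxonomy,
        # plant on moderately abundant taxa (~1% each) so phylum-level
        # structure such as the F/B shift is carried by the planted set
        baseline_overrides={t: 3.0 for t, _, _ in planted},
        seed=seed,
    )
    table, design = generate_community(cspec)

    pspec = PhenotypeSpec(
        base_level=2.0,
        coupled_taxa=((2, 0.35), (0, -0.25)),  # taxon 2: model 2; taxon 0: model 1
        noise_sd=0.15,
        seed=seed + 1,
    )
    phenotype = generate_phenotype(table, design, pspec)

    oftt = generate_kinetics(
        KineticsSpec(
            assay="oftt",
            timepoints=OFTT_TIMEPOINTS,
            group_params={
                "ND": {"baseline": 1.0, "amplitude": 1.0, "tpeak": 300.0},
                "HFD": {"baseline": 2.0, "amplitude": 3.0, "tpeak": 330.0},
                "HFD-T070": {"baseline": 1.5, "amplitude": 1.8, "tpeak": 300.0},
            },
            n_animals=13,
            noise_sd=0.1,
            seed=seed + 2,
        )
    )
    poloxamer = generate_kinetics(
        KineticsSpec(
            assay="poloxamer",
            timepoints=POLOXAMER_TIMEPOINTS,
            group_params={
                "ND": {"baseline": 1.0, "slope": 0.015},
                "HFD": {"baseline": 2.0, "slope": 0.030},
                "HFD-T070": {"baseline": 1.5, "slope": 0.022},
            },
            n_animals=13,
            noise_sd=0.05,
            seed=seed + 3,
        )
    )
    isotopes = {
        "HFD": generate_isotope_records(14, 70.0, seed=seed + 4, noise_sd=0.1),
        "HFD-T070": generate_isotope_records(14, 61.6, seed=seed + 5, noise_sd=0.1),
    }
    ct = generate_ct_table(
        groups={"ND": 8, "HFD": 8, "HFD-T070": 8},
        control_group="ND",
        log2_fold={"HFD": 1.5, "HFD-T070": 0.5},
        noise_sd=0.2,
        seed=seed + 6,
    )
    return {
        "community_spec": cspec,
        "table": table,
        "design": design,
        "phenotype_spec": pspec,
        "phenotype": phenotype,
        "oftt": oftt,
        "poloxamer": poloxamer,
        "isotopes": isotopes,
        "ct": ct,
    }


# ---------------------------------------------------------------------------
# Writers (all TSV/CSV with a provenance comment line)


def write_study(study: dict, outdir) -> None:
    """Write all inputs of a generated study to TSV/CSV files under `outdir`."""
    from pathlib import Path

    from .tables import write_abundance_tsv, write_metadata_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cspec = study["community_spec"]
    note = provenance_header(cspec)
    write_abundance_tsv(study["table"], out / "abundance.tsv", header_note=note)
    meta = study["design"].metadata.copy()
    meta["total_cholesterol"] = study["phenotype"].reindex(meta["sample"]).to_numpy()
    write_metadata_tsv(meta, out / "metadata.tsv", header_note=note)

    for name in ("oftt", "poloxamer"):
        rows = [
            {"animal": s.animal, "group": s.group, "time_min": t, "concentration": c}
            for s in study[name]
            for t, c in zip(s.times, s.concentrations)
        ]
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(f"# {note}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)

    iso_rows = []
    for group, recs in study["isotopes"].items():
        for r in recs:
            iso_rows.append(
                {
                    "animal": f"{group}_{r.animal}",
                    "group": group,
                    "dose_oral_dpm": r.dose_oral,
                    "dose_iv_dpm": r.dose_iv,
                    "serum_oral_dpm": r.serum_oral,
                    "serum_iv_dpm": r.serum_iv,
                    "aliquot_ul": r.aliquot_ul,
                }
            )
    with open(out / "isotopes.csv", "w") as fh:
        fh.write(f"# {note}\n")
        pd.DataFrame(iso_rows).to_csv(fh, index=False)

    with open(out / "ct.csv", "w") as fh:
        fh.write(f"# {note}\n")
        study["ct"].to_csv(fh, index=False)
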