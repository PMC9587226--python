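"""Ground-truth simulation for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* proteomes with membrane topologies, signal peptides, transmembrane spans,
  domains and functional regions, plus Ser/Thr-rich (mucin-like) stretches
  where clustered sites can live;
* true glycosites placed on S/T (rarely Y), a configurable fraction of them
  in dense clusters, each supported by ETD PSMs with ptmRS-like localization
  probabilities and by HCD partner spectra carrying six-plex-style reporter
  intensities with multiplicative knockout effects and log-normal noise;
* matched protein-level (non-enriched) intensities, flat except for a
  configurable set of abundance-changed proteins;
* MS1 glycoform peak tables drawn from known occupancies and xTn mixing
  proportions, including labeled out-of-spec decoy peaks to exercise the
  acceptance filters.

Randomness comes from one seed; each stage derives its own stream by a fixed
offset so adding a stage never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ConfigurationError,
    FeatureAnnotation,
    GlycoPSM,
    GlycoformPeak,
    ProteinRecord,
)

KNOCKOUT_PANEL = (
    "T1KO", "T2KO", "T3KO", "T6KO", "T7KO", "T10KO", "T11KO", "T14KO", "T18KO",
)
DOMAIN_LABELS = (
    "Fibronectin type-III",
    "Ig-like C2-type",
    "Thioredoxin",
    "LDL-receptor class A",
    "Cadherin",
    "EGF-like",
)
_AA = "ACDEFGHIKLMNPQRVWY"  # S/T handled via enrichment draw
_TOPOLOGY_CYCLE = ("type_I", "type_II", "secreted", "other", "multipass")

# occupancy mixture: (weight, low, high); ~60% of regions highly occupied,
# 11% intermediate, ~30% low to very low
DEFAULT_OCCUPANCY_MIXTURE = (
    (0.60, 0.75, 1.0),
    (0.11, 0.25, 0.75),
    (0.29, 0.001, 0.1),
)


@dataclass
class SimConfig:
    """All knobs of the simulation; defaults are the study conditions."""

    seed: int = 0
    n_proteins: int = 40
    length_range: tuple[int, int] = (250, 700)
    n_sites: int = 200
    patch_fraction: float = 0.15
    n_conditions: int = 10  # WT + 9 knockouts
    replicates_per_condition: int = 3
    effect_size: float = 0.1
    cv_noise: float = 0.2
    frac_isoform_specific: float = 0.5
    frac_below_cutoff: float = 0.08
    frac_multisite: float = 0.1
    mucin_fraction: float = 0.4
    domain_fraction: float = 0.7
    functional_fraction: float = 0.3
    abundance_changed_fraction: float = 0.0
    abundance_effect: float = 0.3
    occupancy_mixture: tuple = DEFAULT_OCCUPANCY_MIXTURE
    exact_one_fraction: float = 0.1
    max_tn: int = 5
    decoy_fraction: float = 0.0
    ppm_window: float = 1.5
    idotp_min: float = 0.85
    rt_window_min: float = 5.0

    def validate(self) -> None:
        fractions = {
            "patch_fraction": self.patch_fraction,
            "frac_isoform_specific": self.frac_isoform_specific,
            "frac_below_cutoff": self.frac_below_cutoff,
            "frac_multisite": self.frac_multisite,
            "mucin_fraction": self.mucin_fraction,
            "domain_fraction": self.domain_fraction,
            "functional_fraction": self.functional_fraction,
            "abundance_changed_fraction": self.abundance_changed_fraction,
            "exact_one_fraction": self.exact_one_fraction,
            "decoy_fraction": self.decoy_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.replicates_per_condition < 2:
            raise ConfigurationError("replicates_per_condition must be >= 2")
        if not (0.0 < self.effect_size <= 1.0):
            raise ConfigurationError("effect_size must lie in (0, 1]")
        if self.cv_noise < 0:
            raise ConfigurationError("cv_noise must be >= 0")
        if self.n_conditions < 1:
            raise ConfigurationError("need at least the wild-type condition")
        if self.max_tn < 1:
            raise ConfigurationError("max_tn must be >= 1")
        lo, hi = self.length_range
        if lo > hi or (self.n_proteins > 0 and lo < 120):
            raise ConfigurationError(
                f"length_range {self.length_range} too small to host the "
                "requested features (need min length >= 120)"
            )
        weight = sum(w for w, _, _ in self.occupancy_mixture)
        if abs(weight - 1.0) > 1e-9:
            raise ConfigurationError("occupancy mixture weights must sum to 1")

    def conditions(self) -> list[str]:
        kos = list(KNOCKOUT_PANEL) + [
            f"KO{i}" for i in range(len(KNOCKOUT_PANEL) + 1, self.n_conditions)
        ]
        return ["WT"] + kos[: self.n_conditions - 1]

    def channels(self) -> list[str]:
        return [
            f"{cond}:{r}"
            for cond in self.conditions()
            for r in range(1, self.replicates_per_condition + 1)
        ]


@dataclass
class GroundTruth:
    """Everything downstream recovery tests compare against."""

    true_sites: list[tuple[str, int, str]] = field(default_factory=list)
    site_targets: dict[tuple[str, int], Optional[str]] = field(default_factory=dict)
    true_occupancy: dict[tuple, float] = field(default_factory=dict)
    true_xtn: dict[tuple, list[float]] = field(default_factory=dict)
    below_cutoff_sites: set[tuple[str, int]] = field(default_factory=set)
    patch_clusters: list[list[tuple[str, int]]] = field(default_factory=list)
    abundance_changed: dict[str, str] = field(default_factory=dict)
    protein_table: Optional[pd.DataFrame] = None
    peak_decoys: dict[int, str] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, extra])


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise(rng: np.random.Generator, sigma: float) -> float:
    # median-preserving multiplicative noise: median(ratio) is exact
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


# ---------------------------------------------------------------------------
# Stage 1: proteome


def simulate_proteome(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[FeatureAnnotation]]:
    """Generate a proteome with topology and feature annotations.

    Type-I proteins get a signal peptide and a C-terminal-proximal
    transmembrane span (extracellular N side); type-II an N-terminal-proximal
    one (extracellular C side); secreted proteins a signal peptide only.
    A ``mucin_fraction`` of proteins receives one 30-residue S/T-rich run so
    clustered sites have somewhere realistic to live.
    """
    config.validate()
    rng = _rng(config, 1)
    proteome: list[ProteinRecord] = []
    features: list[FeatureAnnotation] = []

    for i in range(config.n_proteins):
        accession = f"SIM{i:04d}"
        topology = _TOPOLOGY_CYCLE[i % len(_TOPOLOGY_CYCLE)]
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _random_sequence(rng, length)

        mature_start, mature_end = 1, length
        if topology in ("type_I", "secreted"):
            sp_end = int(rng.integers(16, 25))
            features.append(FeatureAnnotation(accession, "signal_peptide", 1, sp_end))
            mature_start = sp_end + 1
        if topology == "type_I":
            tm_start = length - int(rng.integers(25, 45))
            features.append(
                FeatureAnnotation(accession, "transmembrane", tm_start, tm_start + 20)
            )
            mature_end = tm_start - 1  # extracellular part
        elif topology == "type_II":
            tm_start = int(rng.integers(25, 40))
            features.append(
                FeatureAnnotation(accession, "transmembrane", tm_start, tm_start + 20)
            )
            mature_start = tm_start + 21
        elif topology == "multipass":
            for tm_start in (40, length // 2):
                features.append(
                    FeatureAnnotation(
                        accession, "transmembrane", tm_start, tm_start + 20
                    )
                )

        if rng.random() < config.mucin_fraction and mature_end - mature_start > 80:
            run_start = int(
                rng.integers(mature_start + 10, mature_end - 40)
            )
            seq = _plant_mucin_run(rng, seq, run_start, 30)

        if topology != "multipass" and rng.random() < config.domain_fraction:
            features.extend(
                _place_domains(rng, accession, mature_start, mature_end)
            )
        if rng.random() < config.functional_fraction and mature_end - mature_start > 60:
            fr_start = int(rng.integers(mature_start, mature_end - 15))
            features.append(
                FeatureAnnotation(
                    accession, "functional_region", fr_start, fr_start + 12,
                    "proteolytic cleavage",
                )
            )

        proteome.append(ProteinRecord(accession, seq, topology=topology))

    return proteome, features


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # ~18% S/T overall; the remaining mass spread over the other residues
    letters = list(_AA) + ["S", "T"]
    p = np.full(len(letters), 0.82 / len(_AA))
    p[-2:] = 0.09
    return "".join(rng.choice(letters, size=length, p=p))


def _plant_mucin_run(
    rng: np.random.Generator, seq: str, start: int, run_len: int
) -> str:
    """Overwrite a stretch with ~55% S/T content (mucin-like)."""
    chars = list(seq)
    for offset in range(run_len):
        idx = start - 1 + offset
        if idx >= len(chars):
            break
        if rng.random() < 0.55:
            chars[idx] = "S" if rng.random() < 0.5 else "T"
    return "".join(chars)


def _place_domains(
    rng: np.random.Generator, accession: str, lo: int, hi: int
) -> list[FeatureAnnotation]:
    domains = []
    n = int(rng.integers(1, 5))
    cursor = lo + int(rng.integers(5, 30))
    for k in range(n):
        dom_len = int(rng.integers(40, 61))
        if cursor + dom_len > hi:
            break
        label = DOMAIN_LABELS[int(rng.integers(0, len(DOMAIN_LABELS)))]
        domains.append(
            FeatureAnnotation(accession, "domain", cursor, cursor + dom_len - 1, label)
        )
        cursor += dom_len + int(rng.integers(20, 81))
    return domains


# ---------------------------------------------------------------------------
# Stage 2: sites + PSMs


def simulate_sites_and_psms(
    config: SimConfig,
    proteome: Sequence[ProteinRecord],
    features: Sequence[FeatureAnnotation] = (),
) -> tuple[GroundTruth, list[GlycoPSM]]:
    """Place true glycosites and emit the glycoPSM evidence for them.

    ``patch_fraction`` of the sites is laid down in clusters of >= 5 within
    25 residues (inside the planted S/T-rich runs); the rest are isolated,
    kept > 25 residues from every other site so they can never join a patch.
    Each site yields at least one ETD PSM (localization probability above the
    95% cutoff except for a ``frac_below_cutoff`` subset) plus an HCD partner
    carrying the reporter intensities: baseline x effect_size in the channel
    of the knockout targeting the site, x log-normal noise everywhere.
    """
    config.validate()
    rng = _rng(config, 2)
    sigma = _lognormal_sigma(config.cv_noise)
    conditions = config.conditions()
    ko_conditions = conditions[1:]
    truth = GroundTruth()

    site_positions = _place_sites(config, rng, proteome, truth)
    if len(site_positions) < config.n_sites:
        raise ConfigurationError(
            f"could only place {len(site_positions)} of {config.n_sites} sites; "
            "not enough S/T residues (raise n_proteins or length_range)"
        )

    # isoform-specific target assignment, round-robin over the knockouts
    n_specific = round(config.frac_isoform_specific * len(site_positions))
    order = rng.permutation(len(site_positions))
    specific_idx = set(order[:n_specific].tolist()) if ko_conditions else set()
    for rank, idx in enumerate(sorted(specific_idx)):
        acc, pos, _ = site_positions[idx]
        truth.site_targets[(acc, pos)] = ko_conditions[rank % len(ko_conditions)]
    for idx, (acc, pos, _) in enumerate(site_positions):
        truth.site_targets.setdefault((acc, pos), None)

    n_below = round(config.frac_below_cutoff * len(site_positions))
    below_idx = set(order[::-1][:n_below].tolist())

    sequences = {p.accession: p.sequence for p in proteome}
    psms: list[GlycoPSM] = []
    occ_rng = _rng(config, 2, 1)
    for idx, (acc, pos, residue) in enumerate(site_positions):
        seq = sequences[acc]
        pep_start, pep_end = pos - 5, pos + 6
        peptide = seq[pep_start - 1 : pep_end]
        target = truth.site_targets[(acc, pos)]
        intensities = _reporter_intensities(
            rng, config, sigma, conditions, target
        )
        prob = (
            float(rng.uniform(55.0, 94.0))
            if idx in below_idx
            else float(rng.uniform(96.0, 100.0))
        )
        if idx in below_idx:
            truth.below_cutoff_sites.add((acc, pos))
        precursor = f"{acc}:{pos}"
        score = float(rng.uniform(250.0, 500.0))
        rel_pos = pos - pep_start + 1
        psms.append(
            GlycoPSM(peptide, acc, pep_start, pep_end, 1, 0, [rel_pos], [prob],
                     "ETD", score, dict(intensities), precursor)
        )
        psms.append(
            GlycoPSM(peptide, acc, pep_start, pep_end, 1, 0, [], [],
                     "HCD", float(rng.uniform(50.0, 200.0)), dict(intensities),
                     precursor)
        )
        if rng.random() < 0.3:  # a second, lower-quality ETD PSM
            psms.append(
                GlycoPSM(peptide, acc, pep_start, pep_end, 1, 0, [rel_pos],
                         [prob], "ETD", score - float(rng.uniform(10.0, 100.0)),
                         dict(intensities), precursor + ":b")
            )

        # occupancy ground truth, one peptide region per single-site peptide
        region = (acc, pep_start, pep_end, peptide)
        occ, xtn = _draw_occupancy(occ_rng, config)
        truth.true_occupancy[region] = occ
        truth.true_xtn[region] = xtn

    psms.extend(_multisite_psms(config, rng, sigma, conditions, truth, sequences))
    truth.true_sites = sorted(site_positions)
    truth.protein_table = _protein_table(config, rng, sigma, proteome, truth)
    return truth, psms


def _place_sites(
    config: SimConfig,
    rng: np.random.Generator,
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
) -> list[tuple[str, int, str]]:
    chosen: list[tuple[str, int, str]] = []
    used: dict[str, list[int]] = {}
    n_patch_sites = round(config.n_sites * config.patch_fraction)

    def far_enough(acc: str, pos: int, min_gap: int) -> bool:
        return all(abs(pos - q) > min_gap for q in used.get(acc, ()))

    # clusters first: windows of 25 residues holding >= 5 S/T
    placed_in_patches = 0
    order = rng.permutation(len(proteome))
    for pi in order:
        if placed_in_patches >= n_patch_sites:
            break
        protein = proteome[pi]
        seq = protein.sequence
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "ST"]
        for left in sty:
            if placed_in_patches >= n_patch_sites:
                break
            if left < 10 or left > len(seq) - 35:
                continue
            members = [p for p in sty if left <= p <= left + 24]
            if len(members) < 5:
                continue
            if not all(far_enough(protein.accession, p, 25) for p in members):
                continue
            cluster = members[: min(len(members), 8)]
            for p in cluster:
                chosen.append((protein.accession, p, seq[p - 1]))
                used.setdefault(protein.accession, []).append(p)
            truth.patch_clusters.append(
                [(protein.accession, p) for p in cluster]
            )
            placed_in_patches += len(cluster)

    # isolated sites, > 25 residues from anything already placed
    candidates = []
    for protein in proteome:
        seq = protein.sequence
        for i, aa in enumerate(seq):
            pos = i + 1
            if 10 <= pos <= len(seq) - 10 and (
                aa in "ST" or (aa == "Y" and rng.random() < 0.02)
            ):
                candidates.append((protein.accession, pos, aa))
    rng.shuffle(candidates)
    for acc, pos, aa in candidates:
        if len(chosen) >= config.n_sites:
            break
        if far_enough(acc, pos, 25):
            chosen.append((acc, pos, aa))
            used.setdefault(acc, []).append(pos)
    return chosen[: config.n_sites]


def _reporter_intensities(
    rng: np.random.Generator,
    config: SimConfig,
    sigma: float,
    conditions: Sequence[str],
    target: Optional[str],
) -> dict[str, float]:
    baseline = 10.0 ** rng.uniform(4.5, 5.5)
    out = {}
    for cond in conditions:
        effect = config.effect_size if (target is not None and cond == target) else 1.0
        for rep in range(1, config.replicates_per_condition + 1):
            out[f"{cond}:{rep}"] = baseline * effect * _noise(rng, sigma)
    return out


def _draw_occupancy(
    rng: np.random.Generator, config: SimConfig
) -> tuple[float, list[float]]:
    weights = [w for w, _, _ in config.occupancy_mixture]
    k = int(rng.choice(len(weights), p=np.array(weights) / sum(weights)))
    _, lo, hi = config.occupancy_mixture[k]
    occ = float(rng.uniform(lo, hi))
    if hi >= 1.0 and rng.random() < config.exact_one_fraction:
        occ = 1.0
    tn = int(rng.integers(1, config.max_tn + 1))
    xtn = rng.dirichlet(np.full(tn, 2.0)).tolist() if tn > 1 else [1.0]
    return occ, xtn


def _multisite_psms(
    config: SimConfig,
    rng: np.random.Generator,
    sigma: float,
    conditions: Sequence[str],
    truth: GroundTruth,
    sequences: dict[str, str],
) -> list[GlycoPSM]:
    """Multi-glycan PSMs over adjacent cluster-site pairs (plus a few
    mixed-evidence singles) to exercise the single-site filter."""
    pairs = []
    for cluster in truth.patch_clusters:
        for (acc, a), (_, b) in zip(cluster, cluster[1:]):
            pairs.append((acc, a, b))
    n_multi = round(config.frac_multisite * len(pairs))
    psms: list[GlycoPSM] = []
    for acc, a, b in pairs[:n_multi]:
        seq = sequences[acc]
        pep_start, pep_end = a - 2, b + 2
        peptide = seq[pep_start - 1 : pep_end]
        positions = [a - pep_start + 1, b - pep_start + 1]
        probs = [float(rng.uniform(96.0, 100.0)) for _ in positions]
        intensities = _reporter_intensities(rng, config, sigma, conditions, None)
        precursor = f"{acc}:{a}-{b}"
        psms.append(
            GlycoPSM(peptide, acc, pep_start, pep_end, 2, 0, positions, probs,
                     "ETD", float(rng.uniform(250.0, 500.0)), dict(intensities),
                     precursor)
        )
        psms.append(
            GlycoPSM(peptide, acc, pep_start, pep_end, 2, 0, [], [], "HCD",
                     float(rng.uniform(50.0, 200.0)), dict(intensities), precursor)
        )
        if rng.random() < 0.2:  # mixed evidence: same peptide with one glycan
            psms.append(
                GlycoPSM(peptide, acc, pep_start, pep_end, 1, 0, [positions[0]],
                         [probs[0]], "ETD", float(rng.uniform(250.0, 500.0)),
                         dict(intensities), precursor + ":m")
            )
    return psms


def _protein_table(
    config: SimConfig,
    rng: np.random.Generator,
    sigma: float,
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
) -> pd.DataFrame:
    conditions = config.conditions()
    ko_conditions = conditions[1:]
    n_changed = round(config.abundance_changed_fraction * len(proteome))
    glyco_targeted = {acc for (acc, _), ko in truth.site_targets.items() if ko}
    changeable = [p.accession for p in proteome if p.accession not in glyco_targeted]
    for j, acc in enumerate(changeable[:n_changed]):
        truth.abundance_changed[acc] = ko_conditions[j % len(ko_conditions)]

    rows = {}
    for protein in proteome:
        baseline = 10.0 ** rng.uniform(5.0, 6.0)
        row = {}
        for cond in conditions:
            effect = (
                config.abundance_effect
                if truth.abundance_changed.get(protein.accession) == cond
                else 1.0
            )
            for rep in range(1, config.replicates_per_condition + 1):
                row[f"{cond}:{rep}"] = baseline * effect * _noise(rng, sigma)
        rows[protein.accession] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# Stage 3: MS1 glycoform peak tables


def simulate_peak_table(
    config: SimConfig,
    truth: GroundTruth,
    source: str = "COSMC",
) -> list[GlycoformPeak]:
    """MS1 peak areas for every truth region, per replicate.

    Per region and replicate: non-glyco area = total x (1 - occupancy) and
    glycoform areas = total x occupancy x xTn proportion, each perturbed by
    log-normal noise; fully occupied regions emit no non-glyco row at all
    (detection absence). Areas are split over two charge states. A
    ``decoy_fraction`` of regions receives one extra out-of-spec peak whose
    index and violated filter are recorded in ``truth.peak_decoys``.

    ``source`` names the sample (e.g. "COSMC" vs "WT") and seeds an
    independent noise stream, so two sources share the truth but not the
    noise.
    """
    config.validate()
    rng = _rng(config, 3, zlib.crc32(source.encode()) & 0x7FFFFFFF)
    sigma = _lognormal_sigma(config.cv_noise)
    peaks: list[GlycoformPeak] = []
    truth.peak_decoys = {}
    violations = ("ppm", "idotp", "rt", "id_score")
    decoy_cycle = 0

    for region in sorted(truth.true_occupancy):
        acc, start, end, peptide = region
        occ = truth.true_occupancy[region]
        xtn = truth.true_xtn[region]
        total = 10.0 ** rng.uniform(5.5, 6.5)
        for rep in range(1, config.replicates_per_condition + 1):
            replicate = str(rep)
            if occ < 1.0:
                peaks.extend(
                    _split_charges(rng, config, region, 0, replicate,
                                   total * (1.0 - occ) * _noise(rng, sigma))
                )
            for form, proportion in enumerate(xtn, start=1):
                if proportion == 0.0:
                    continue
                peaks.extend(
                    _split_charges(rng, config, region, form, replicate,
                                   total * occ * proportion * _noise(rng, sigma))
                )
        if rng.random() < config.decoy_fraction:
            reason = violations[decoy_cycle % len(violations)]
            decoy_cycle += 1
            peaks.append(_decoy_peak(rng, config, region, reason, total))
            truth.peak_decoys[len(peaks) - 1] = reason
    return peaks


def _in_spec(
    rng: np.random.Generator, config: SimConfig
) -> tuple[float, float, float, float]:
    return (
        float(rng.uniform(-0.8 * config.ppm_window, 0.8 * config.ppm_window)),
        float(rng.uniform(config.idotp_min + 0.03, 1.0)),
        float(rng.uniform(-0.6 * config.rt_window_min, 0.6 * config.rt_window_min)),
        float(rng.uniform(200.0, 600.0)),
    )


def _split_charges(
    rng: np.random.Generator,
    config: SimConfig,
    region: tuple,
    glycoform: int,
    replicate: str,
    area: float,
) -> list[GlycoformPeak]:
    acc, start, end, peptide = region
    frac = float(rng.uniform(0.4, 0.9))
    out = []
    for charge, part in ((2, frac), (3, 1.0 - frac)):
        ppm, idotp, rt, score = _in_spec(rng, config)
        out.append(
            GlycoformPeak(acc, start, end, peptide, glycoform, charge,
                          area * part, ppm, idotp, rt, replicate, score)
        )
    return out


def _decoy_peak(
    rng: np.random.Generator,
    config: SimConfig,
    region: tuple,
    reason: str,
    total: float,
) -> GlycoformPeak:
    acc, start, end, peptide = region
    ppm, idotp, rt, score = _in_spec(rng, config)
    if reason == "ppm":
        ppm = float(rng.choice([-1.0, 1.0])) * float(
            rng.uniform(config.ppm_window, 3.0 * config.ppm_window)
        )
    elif reason == "idotp":
        idotp = float(rng.uniform(0.3, config.idotp_min))
    elif reason == "rt":
        rt = float(rng.choice([-1.0, 1.0])) * float(
            rng.uniform(config.rt_window_min, 3.0 * config.rt_window_min)
        )
    elif reason == "id_score":
        score = float(rng.uniform(0.0, 199.0))
    return GlycoformPeak(acc, start, end, peptide, 1, 2,
                         total * float(rng.uniform(0.01, 0.2)), ppm, idotp, rt,
                         "1", score)
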