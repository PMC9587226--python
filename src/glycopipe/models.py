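"""Core record types shared across the pipeline.

All protein coordinates are 1-based and inclusive (UniProt convention).
Reporter channels are labeled ``condition:replicate`` (e.g. ``WT:1``,
``T2KO:3``); the condition prefix carries the experimental grouping.
A missing intensity is ``None`` ("not detected") and is distinct from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

TOPOLOGIES = ("type_I", "type_II", "secreted", "multipass", "other")
FEATURE_KINDS = ("signal_peptide", "transmembrane", "domain", "functional_region")
FRAG_TYPES = ("ETD", "HCD")
GLYCO_RESIDUES = frozenset("STY")
REGION_CATEGORIES = (
    "domain",
    "stem",
    "linker",
    "terminus",
    "functional_region",
    "unassigned",
)


class ValidationError(ValueError):
    """Raised when an input record violates a documented contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration cannot produce a valid simulation/run."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry with membrane topology annotation."""

    accession: str
    sequence: str
    topology: str = "other"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())
        if self.topology not in TOPOLOGIES:
            raise ValidationError(
                f"{self.accession}: unknown topology {self.topology!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A UniProt-style protein feature interval (1-based inclusive)."""

    accession: str
    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.accession} {self.kind}: bad interval {self.start}-{self.end}"
            )
        if self.kind == "domain" and not self.label:
            raise ValidationError(f"{self.accession}: domain feature needs a label")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GlycoPSM:
    """One glycopeptide-spectrum match.

    ``site_positions`` are peptide-relative (1-based); paired localization
    probabilities are percentages as reported by ptmRS-style scoring.
    ``intensities`` maps channel label -> reporter intensity (None = missing).
    """

    peptide: str
    accession: str
    pep_start: int
    pep_end: int
    hexnac_count: int
    hex_count: int
    site_positions: list[int]
    site_probabilities: list[float]
    frag_type: str
    psm_score: float
    intensities: dict[str, Optional[float]] = field(default_factory=dict)
    precursor_id: str = ""

    def __post_init__(self) -> None:
        if self.frag_type not in FRAG_TYPES:
            raise ValidationError(f"unknown frag_type {self.frag_type!r}")
        if len(self.site_positions) != len(self.site_probabilities):
            raise ValidationError(
                f"{self.accession} {self.peptide}: {len(self.site_positions)} site "
                f"positions vs {len(self.site_probabilities)} probabilities"
            )
        if self.pep_end - self.pep_start + 1 != len(self.peptide):
            raise ValidationError(
                f"{self.accession} {self.peptide}: coordinates "
                f"{self.pep_start}-{self.pep_end} do not span the peptide"
            )
        if self.hexnac_count < 1:
            raise ValidationError("glycoPSM must carry at least one HexNAc")
        for pos in self.site_positions:
            if not (1 <= pos <= len(self.peptide)):
                raise ValidationError(
                    f"{self.peptide}: site position {pos} outside peptide"
                )
            if self.peptide[pos - 1] not in GLYCO_RESIDUES:
                raise ValidationError(
                    f"{self.peptide}: position {pos} is "
                    f"{self.peptide[pos - 1]}, not S/T/Y"
                )
        for channel, value in self.intensities.items():
            if value is not None and value < 0:
                raise ValidationError(
                    f"{self.peptide}: negative intensity {value} in {channel}"
                )

    @property
    def glycopeptide_key(self) -> tuple[str, int, int, str]:
        """Identity of the glycopeptide this PSM supports."""
        return (self.accession, self.pep_start, self.pep_end, self.peptide)


@dataclass
class GlycoSite:
    """A non-redundant protein-coordinate O-glycosite.

    Unambiguous sites have a single confident position; ambiguous sites carry
    the S/T/Y span of the supporting peptide as ``ambiguity_range`` and use its
    first residue as the nominal position.
    """

    accession: str
    position: int
    residue: str
    status: str  # "unambiguous" | "ambiguous"
    ambiguity_range: Optional[tuple[int, int]] = None
    n_psms: int = 1
    best_psm: Optional[GlycoPSM] = None

    def __post_init__(self) -> None:
        if self.status not in ("unambiguous", "ambiguous"):
            raise ValidationError(f"bad site status {self.status!r}")
        if self.status == "unambiguous" and self.ambiguity_range is not None:
            raise ValidationError("unambiguous site must not carry a range")
        if self.status == "ambiguous" and self.ambiguity_range is None:
            raise ValidationError("ambiguous site needs an ambiguity_range")

    @property
    def key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass(frozen=True)
class RegionAssignment:
    """Placement of one unambiguous site into a protein-region category."""

    site: GlycoSite
    category: str
    feature: Optional[FeatureAnnotation] = None
    distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in REGION_CATEGORIES:
            raise ValidationError(f"unknown region category {self.category!r}")


@dataclass
class DomainStats:
    """Per-domain-type glycosylation summary over catalog glycoproteins."""

    domain_label: str
    n_domains_total: int
    n_domains_glycosylated: int
    rate: float
    sites_per_domain: list[int]
    position_bins: list[int]  # 10 bins, N- to C-terminal deciles


@dataclass
class Patch:
    """A high-density O-glycan patch (mucin-like region).

    Extent is first-to-last member site; ``density`` is sites per residue of
    that extent.
    """

    accession: str
    start: int
    end: int
    n_sites: int
    member_sites: list[int]
    density: float

    def __post_init__(self) -> None:
        if list(self.member_sites) != sorted(set(self.member_sites)):
            raise ValidationError("patch member sites must be strictly increasing")


@dataclass
class RegulationCall:
    """Per-site, per-knockout differential result."""

    accession: str
    position: int
    knockout: str
    fold_change: float
    log2_fc: float
    p_raw: float
    p_adj: float
    call: str  # "down" | "up" | "unchanged" | "untested"
    isoform_specific: bool = False
    shared: bool = False
    protein_flag: str = ""  # e.g. "protein-unquantified"

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass
class GlycoformPeak:
    """One MS1 chromatographic peak for a peptide glycoform.

    ``glycoform`` is the HexNAc count (0 = the non-glycosylated peptide);
    ``composition`` optionally names an elaborated wild-type glycan.
    """

    accession: str
    region_start: int
    region_end: int
    peptide: str
    glycoform: int
    charge: int
    area: float
    mass_error_ppm: float
    idotp: float
    rt_delta_min: float
    replicate: str
    id_score: float
    composition: str = ""
    iso_rel_abund: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError("peak area must be >= 0")
        if not (0.0 <= self.idotp <= 1.0):
            raise ValidationError("idotp must lie in [0, 1]")
        if self.glycoform < 0:
            raise ValidationError("glycoform HexNAc count must be >= 0")

    @property
    def region_key(self) -> tuple[str, int, int, str]:
        return (self.accession, self.region_start, self.region_end, self.peptide)


@dataclass
class OccupancyRecord:
    """Occupancy estimate for one peptide region.

    ``glyco_ratio`` is None when the non-glycosylated form was never detected
    (``high_flag``); ``xtn_percent`` holds integer percentages for 1..tn_max
    HexNAc glycoforms (report parity), ``xtn_raw`` the unrounded values.
    """

    accession: str
    region_start: int
    region_end: int
    peptide: str
    tn_max: int
    glyco_ratio: Optional[float]
    sd: Optional[float]
    xtn_percent: list[int]
    xtn_raw: list[float]
    high_flag: bool
    n_replicates: int
    partial_detection: bool = False

    @property
    def region_key(self) -> tuple[str, int, int, str]:
        return (self.accession, self.region_start, self.region_end, self.peptide)

    @property
    def ratio_label(self) -> str:
        return "High" if self.high_flag else f"{self.glyco_ratio:.2f}"
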