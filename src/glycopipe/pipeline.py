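"""End-to-end orchestration: catalog -> regions -> patches -> differential
-> occupancy, with a summary and a machine-readable run manifest.

Every stage logs input row counts and filter outcomes; the summary embeds a
hash of the effective configuration so runs are auditable. After writing,
the summary counts are re-derived from the output tables and checked (an
internal consistency audit)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import io_tables
from .differential import (
    assign_isoform_specificity,
    build_site_table,
    normalize_total,
    protein_abundance_filter,
    summarize_panel,
    test_sites,
)
from .models import ValidationError
from .occupancy import (
    classify_occupancy,
    compute_occupancy_table,
    filter_peaks,
)
from .patch_finder import find_patches_catalog
from .region_mapper import classify_site, domain_statistics, summarize_regions
from .site_catalog import build_catalog

log = logging.getLogger("glycopipe")


@dataclass
class PipelineConfig:
    """Input paths, per-stage parameters and the output directory."""

    fasta: Path
    features: Path
    psms: Path
    out_dir: Path
    protein_table: Optional[Path] = None
    peaks: Optional[Path] = None
    prob_cutoff: float = 95.0
    stem_window: int = 50
    linker_max: int = 100
    terminus_window: int = 10
    patch_window: int = 25
    patch_min_sites: int = 5
    alpha: float = 0.05
    down_fc: float = 0.5
    up_fc: float = 2.0
    use_raw_p: bool = False
    ppm_window: float = 1.5
    idotp_min: float = 0.85
    rt_window_min: float = 5.0
    min_id_score: float = 200.0
    seed: int = 0

    def parameters(self) -> dict:
        # out_dir is deliberately excluded: the same analysis written to two
        # places must produce identical tables and manifests
        out = {}
        for key, value in self.__dict__.items():
            if key == "out_dir":
                continue
            out[key] = str(value) if isinstance(value, Path) else value
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.parameters(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("fasta", "features", "psms"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"input {name} not found: {path}")
        for name in ("protein_table", "peaks"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input {name} not found: {path}")


@dataclass
class PipelineResult:
    out_dir: Path
    summary: dict
    catalog: list = field(default_factory=list)
    patches: list = field(default_factory=list)
    calls: list = field(default_factory=list)
    occupancy: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> PipelineResult:
    """Run every stage in order and write all output tables.

    Stages run catalog -> regions -> patches -> differential -> occupancy;
    optional inputs (protein table, peak table) switch their stage off with a
    note in the summary instead of failing. Outputs are byte-stable for a
    fixed config."""
    config.validate()
    if dry_run:
        return PipelineResult(out_dir=config.out_dir, summary={"dry_run": True})
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"skipped": []}

    proteome = io_tables.read_fasta(config.fasta)
    features = io_tables.read_features(config.features)
    psms = io_tables.read_psm_table(config.psms)
    log.info("inputs: %d proteins, %d features, %d PSMs",
             len(proteome), len(features), len(psms))

    # --- catalog
    catalog = build_catalog(psms, proteome, prob_cutoff=config.prob_cutoff)
    io_tables.write_catalog(out / "site_catalog.tsv", catalog)
    unambiguous = [s for s in catalog if s.status == "unambiguous"]
    summary["n_sites"] = len(catalog)
    summary["n_sites_unambiguous"] = len(unambiguous)
    summary["n_glycoproteins"] = len({s.accession for s in catalog})

    # --- regions
    proteins = {p.accession: p for p in proteome}
    features_by_protein: dict[str, list] = {}
    for f in features:
        features_by_protein.setdefault(f.accession, []).append(f)
    assignments = [
        classify_site(
            site, proteins[site.accession],
            features_by_protein.get(site.accession, []),
            stem_window=config.stem_window,
            linker_max=config.linker_max,
            terminus_window=config.terminus_window,
        )
        for site in unambiguous
    ]
    region_summary = summarize_regions(assignments)
    summary["regions"] = {k: {"count": c, "pct": p}
                          for k, (c, p) in region_summary.items()}
    _write_assignments(out / "region_assignments.tsv", assignments)
    stats = domain_statistics(catalog, proteome, features)
    _write_domain_stats(out / "domain_stats.tsv", stats)

    # --- patches
    patches = find_patches_catalog(
        catalog, window=config.patch_window, min_sites=config.patch_min_sites
    )
    io_tables.write_patches(out / "patches.tsv", patches)
    summary["n_patches"] = len(patches)
    summary["max_patch_sites"] = max((p.n_sites for p in patches), default=0)

    # --- differential
    calls: list = []
    if config.protein_table is None:
        summary["skipped"].append("differential (no protein table)")
    else:
        protein_table = io_tables.read_quant_table(config.protein_table)
        site_table, _meta = build_site_table(psms, proteome, config.prob_cutoff)
        if site_table.empty:
            summary["skipped"].append("differential (no quantifiable sites)")
        else:
            site_table = normalize_total(site_table)
            protein_table = normalize_total(protein_table)
            conditions = sorted(
                {c.split(":", 1)[0] for c in site_table.columns}
            )
            if "WT" not in conditions:
                raise ValidationError("differential stage needs WT channels")
            kos = [c for c in conditions if c != "WT"]
            filtered, flags = protein_abundance_filter(
                site_table, protein_table, "WT", kos, alpha=config.alpha
            )
            log.info("protein-abundance filter: %d -> %d sites",
                     len(site_table), len(filtered))
            for ko in kos:
                calls.extend(
                    test_sites(filtered, "WT", ko, alpha=config.alpha,
                               down_fc=config.down_fc, up_fc=config.up_fc,
                               use_raw_p=config.use_raw_p, protein_flags=flags)
                )
            calls = assign_isoform_specificity(calls)
            io_tables.write_regulation(out / "regulation.tsv", calls)
            summary["differential"] = summarize_panel(calls)

    # --- occupancy
    records: list = []
    if config.peaks is None:
        summary["skipped"].append("occupancy (no peak table)")
    else:
        peaks = io_tables.read_peak_table(config.peaks)
        result = filter_peaks(
            peaks, ppm_window=config.ppm_window, idotp_min=config.idotp_min,
            rt_window_min=config.rt_window_min, min_id_score=config.min_id_score,
        )
        log.info("peak filter: %d accepted, %d rejected (%s)",
                 len(result.accepted), len(result.rejected),
                 ",".join(sorted(set(result.reject_reasons))) or "-")
        records = compute_occupancy_table(result.accepted)
        io_tables.write_occupancy(out / "occupancy.tsv", records)
        summary["occupancy_classes"] = {
            k: {"count": c, "fraction": f}
            for k, (c, f) in classify_occupancy(records).items()
        }
        summary["n_occupancy_regions"] = len(records)
        summary["n_peaks_rejected"] = len(result.rejected)

    manifest = {
        "glycopipe_version": __version__,
        "config_hash": config.config_hash(),
        "parameters": config.parameters(),
    }
    summary["config_hash"] = config.config_hash()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    _audit(out, summary)
    return PipelineResult(out_dir=out, summary=summary, catalog=catalog,
                          patches=patches, calls=calls, occupancy=records)


def _write_assignments(path: Path, assignments) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(io_tables._schema_line("region_assignments"))
        fh.write("accession\tposition\tcategory\tfeature\tdistance\n")
        for a in assignments:
            feature = a.feature.label or a.feature.kind if a.feature else ""
            fh.write(
                f"{a.site.accession}\t{a.site.position}\t{a.category}\t"
                f"{feature}\t{'' if a.distance is None else a.distance}\n"
            )


def _write_domain_stats(path: Path, stats) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(io_tables._schema_line("domain_stats"))
        fh.write("domain_label\tn_total\tn_glycosylated\trate\t"
                 "sites_per_domain\tposition_bins\n")
        for d in stats:
            fh.write(
                f"{d.domain_label}\t{d.n_domains_total}\t"
                f"{d.n_domains_glycosylated}\t{d.rate:.6f}\t"
                f"{';'.join(str(v) for v in d.sites_per_domain)}\t"
                f"{';'.join(str(v) for v in d.position_bins)}\n"
            )


def _audit(out: Path, summary: dict) -> None:
    """Re-derive headline counts from the written tables and cross-check."""
    catalog = io_tables.read_catalog(out / "site_catalog.tsv")
    if len(catalog) != summary["n_sites"]:
        raise ValidationError("audit: catalog count mismatch")
    patches = io_tables.read_patches(out / "patches.tsv")
    if len(patches) != summary["n_patches"]:
        raise ValidationError("audit: patch count mismatch")
    if patches and max(p.n_sites for p in patches) != summary["max_patch_sites"]:
        raise ValidationError("audit: max patch size mismatch")
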