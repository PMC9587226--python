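"""Readers and writers for every external table the pipeline touches.

All files are plain text. Coordinates are 1-based inclusive throughout and
every writer emits a schema comment line saying so. Missing values are empty
strings, never "NA" or 0: a missing reporter intensity means "not detected".
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    FeatureAnnotation,
    GlycoPSM,
    GlycoSite,
    GlycoformPeak,
    OccupancyRecord,
    Patch,
    ProteinRecord,
    RegulationCall,
    ValidationError,
)

PathLike = Union[str, Path]

SCHEMA_PREFIX = "# schema: glycopipe"
_COORD_NOTE = "coordinates 1-based inclusive"

_PSM_FIXED_COLS = [
    "peptide",
    "accession",
    "pep_start",
    "pep_end",
    "hexnac_count",
    "hex_count",
    "site_positions",
    "site_probabilities",
    "frag_type",
    "psm_score",
    "precursor_id",
]


def _schema_line(name: str) -> str:
    return f"{SCHEMA_PREFIX}/{name} v1 ({_COORD_NOTE})\n"


def _open_rows(path: PathLike) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a TSV, skipping comment lines; returns (header, [(lineno, row)])."""
    header: Optional[list[str]] = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise ValidationError(f"{path}: empty table (no header)")
    return header, rows


def _require_cols(header: list[str], required: Iterable[str], path: PathLike) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _int_field(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"line {lineno}: non-integer {what} {value!r}") from None


def _float_field(value: str, what: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"line {lineno}: non-numeric {what} {value!r}") from None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA; header first token is the accession.

    An optional ``topology=<value>`` token in the description is honoured
    (written by :func:`write_fasta`); otherwise topology defaults to "other".
    Duplicate accessions are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValidationError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        topology = "other"
        for token in entry.description.split():
            if token.startswith("topology="):
                topology = token.split("=", 1)[1]
        records.append(
            ProteinRecord(accession, str(entry.seq).upper(), topology=topology)
        )
    return records


def write_fasta(path: PathLike, proteome: Iterable[ProteinRecord]) -> None:
    entries = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=f"topology={p.topology}")
        for p in proteome
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature annotations


def read_features(path: PathLike) -> list[FeatureAnnotation]:
    header, rows = _open_rows(path)
    _require_cols(header, ["accession", "kind", "start", "end", "label"], path)
    idx = {c: header.index(c) for c in header}
    features = []
    for lineno, row in rows:
        start = _int_field(row[idx["start"]], "start", lineno)
        end = _int_field(row[idx["end"]], "end", lineno)
        try:
            features.append(
                FeatureAnnotation(
                    accession=row[idx["accession"]],
                    kind=row[idx["kind"]],
                    start=start,
                    end=end,
                    label=row[idx["label"]],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from None
    return features


def write_features(path: PathLike, features: Iterable[FeatureAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("features"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "kind", "start", "end", "label"])
        for f in features:
            writer.writerow([f.accession, f.kind, f.start, f.end, f.label])


# ---------------------------------------------------------------------------
# Glyco-PSM tables


def _channel_columns(header: list[str]) -> list[str]:
    channels = [c for c in header if c not in _PSM_FIXED_COLS]
    for c in channels:
        if ":" not in c:
            raise ValidationError(
                f"channel column {c!r} does not follow condition:replicate"
            )
    return channels


def read_psm_table(path: PathLike) -> list[GlycoPSM]:
    """Read a Proteome-Discoverer-like glycoPSM export.

    Channel columns are every non-fixed column; their headers must follow the
    ``condition:replicate`` pattern. Empty intensity cells mean "not detected".
    """
    header, rows = _open_rows(path)
    _require_cols(header, [c for c in _PSM_FIXED_COLS if c != "precursor_id"], path)
    idx = {c: header.index(c) for c in header}
    channels = _channel_columns(header)
    psms = []
    for lineno, row in rows:
        positions = [
            _int_field(v, "site position", lineno)
            for v in row[idx["site_positions"]].split(";")
            if v != ""
        ]
        probabilities = [
            _float_field(v, "site probability", lineno)
            for v in row[idx["site_probabilities"]].split(";")
            if v != ""
        ]
        intensities: dict[str, Optional[float]] = {}
        for channel in channels:
            cell = row[idx[channel]]
            if cell == "":
                intensities[channel] = None
            else:
                value = _float_field(cell, f"intensity {channel}", lineno)
                if value < 0:
                    raise ValidationError(
                        f"{path} line {lineno}: negative intensity in {channel}"
                    )
                intensities[channel] = value
        try:
            psms.append(
                GlycoPSM(
                    peptide=row[idx["peptide"]],
                    accession=row[idx["accession"]],
                    pep_start=_int_field(row[idx["pep_start"]], "pep_start", lineno),
                    pep_end=_int_field(row[idx["pep_end"]], "pep_end", lineno),
                    hexnac_count=_int_field(
                        row[idx["hexnac_count"]], "hexnac_count", lineno
                    ),
                    hex_count=_int_field(row[idx["hex_count"]], "hex_count", lineno),
                    site_positions=positions,
                    site_probabilities=probabilities,
                    frag_type=row[idx["frag_type"]],
                    psm_score=_float_field(row[idx["psm_score"]], "psm_score", lineno),
                    precursor_id=row[idx["precursor_id"]]
                    if "precursor_id" in idx
                    else "",
                    intensities=intensities,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from None
    return psms


def write_psm_table(path: PathLike, psms: list[GlycoPSM]) -> None:
    channels: list[str] = []
    for psm in psms:
        for c in psm.intensities:
            if c not in channels:
                channels.append(c)
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("psms"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PSM_FIXED_COLS + channels)
        for p in psms:
            row = [
                p.peptide,
                p.accession,
                p.pep_start,
                p.pep_end,
                p.hexnac_count,
                p.hex_count,
                ";".join(str(v) for v in p.site_positions),
                ";".join(repr(v) for v in p.site_probabilities),
                p.frag_type,
                repr(p.psm_score),
                p.precursor_id,
            ]
            for c in channels:
                v = p.intensities.get(c)
                row.append("" if v is None else repr(v))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Site catalog


def write_catalog(path: PathLike, catalog: Iterable[GlycoSite]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("site_catalog"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "position", "residue", "status", "range_start",
             "range_end", "n_psms"]
        )
        for s in catalog:
            lo, hi = s.ambiguity_range if s.ambiguity_range else ("", "")
            writer.writerow(
                [s.accession, s.position, s.residue, s.status, lo, hi, s.n_psms]
            )


def read_catalog(path: PathLike) -> list[GlycoSite]:
    header, rows = _open_rows(path)
    _require_cols(
        header,
        ["accession", "position", "residue", "status", "range_start", "range_end",
         "n_psms"],
        path,
    )
    idx = {c: header.index(c) for c in header}
    sites = []
    for lineno, row in rows:
        rng = None
        if row[idx["range_start"]] != "":
            rng = (
                _int_field(row[idx["range_start"]], "range_start", lineno),
                _int_field(row[idx["range_end"]], "range_end", lineno),
            )
        sites.append(
            GlycoSite(
                accession=row[idx["accession"]],
                position=_int_field(row[idx["position"]], "position", lineno),
                residue=row[idx["residue"]],
                status=row[idx["status"]],
                ambiguity_range=rng,
                n_psms=_int_field(row[idx["n_psms"]], "n_psms", lineno),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Patches (BED-like, but 1-based inclusive)


def write_patches(path: PathLike, patches: Iterable[Patch]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("patches"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "start", "end", "n_sites", "member_sites"])
        for p in patches:
            writer.writerow(
                [p.accession, p.start, p.end, p.n_sites,
                 ";".join(str(v) for v in p.member_sites)]
            )


def read_patches(path: PathLike) -> list[Patch]:
    header, rows = _open_rows(path)
    _require_cols(header, ["accession", "start", "end", "n_sites", "member_sites"], path)
    idx = {c: header.index(c) for c in header}
    patches = []
    for lineno, row in rows:
        members = [int(v) for v in row[idx["member_sites"]].split(";") if v != ""]
        start = _int_field(row[idx["start"]], "start", lineno)
        end = _int_field(row[idx["end"]], "end", lineno)
        patches.append(
            Patch(
                accession=row[idx["accession"]],
                start=start,
                end=end,
                n_sites=_int_field(row[idx["n_sites"]], "n_sites", lineno),
                member_sites=members,
                density=len(members) / (end - start + 1),
            )
        )
    return patches


# ---------------------------------------------------------------------------
# Regulation table (long format: one row per site x knockout)


def write_regulation(path: PathLike, calls: Iterable[RegulationCall]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("regulation"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "position", "knockout", "fold_change", "log2_fc",
             "p_raw", "p_adj", "call", "isoform_specific", "shared", "protein_flag"]
        )
        for c in calls:
            writer.writerow(
                [c.accession, c.position, c.knockout,
                 "" if c.fold_change != c.fold_change else repr(c.fold_change),
                 "" if c.log2_fc != c.log2_fc else repr(c.log2_fc),
                 "" if c.p_raw != c.p_raw else repr(c.p_raw),
                 "" if c.p_adj != c.p_adj else repr(c.p_adj),
                 c.call, int(c.isoform_specific), int(c.shared), c.protein_flag]
            )


# ---------------------------------------------------------------------------
# MS1 glycoform peak tables (Skyline-export-like)

_PEAK_COLS = [
    "accession", "region_start", "region_end", "peptide", "glycoform",
    "composition", "charge", "area", "mass_error_ppm", "idotp",
    "rt_delta_min", "replicate", "id_score", "iso_rel_abund",
]


def read_peak_table(path: PathLike) -> list[GlycoformPeak]:
    header, rows = _open_rows(path)
    _require_cols(header, _PEAK_COLS, path)
    idx = {c: header.index(c) for c in header}
    peaks = []
    for lineno, row in rows:
        iso = row[idx["iso_rel_abund"]]
        peaks.append(
            GlycoformPeak(
                accession=row[idx["accession"]],
                region_start=_int_field(row[idx["region_start"]], "region_start", lineno),
                region_end=_int_field(row[idx["region_end"]], "region_end", lineno),
                peptide=row[idx["peptide"]],
                glycoform=_int_field(row[idx["glycoform"]], "glycoform", lineno),
                composition=row[idx["composition"]],
                charge=_int_field(row[idx["charge"]], "charge", lineno),
                area=_float_field(row[idx["area"]], "area", lineno),
                mass_error_ppm=_float_field(
                    row[idx["mass_error_ppm"]], "mass_error_ppm", lineno
                ),
                idotp=_float_field(row[idx["idotp"]], "idotp", lineno),
                rt_delta_min=_float_field(
                    row[idx["rt_delta_min"]], "rt_delta_min", lineno
                ),
                replicate=row[idx["replicate"]],
                id_score=_float_field(row[idx["id_score"]], "id_score", lineno),
                iso_rel_abund=None if iso == "" else float(iso),
            )
        )
    return peaks


def write_peak_table(path: PathLike, peaks: Iterable[GlycoformPeak]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("peaks"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PEAK_COLS)
        for p in peaks:
            writer.writerow(
                [p.accession, p.region_start, p.region_end, p.peptide, p.glycoform,
                 p.composition, p.charge, repr(p.area), repr(p.mass_error_ppm),
                 repr(p.idotp), repr(p.rt_delta_min), p.replicate, repr(p.id_score),
                 "" if p.iso_rel_abund is None else repr(p.iso_rel_abund)]
            )


# ---------------------------------------------------------------------------
# Occupancy output


def write_occupancy(path: PathLike, records: Iterable[OccupancyRecord]) -> None:
    """Full-precision occupancy table; the ratio column prints 'High' when the
    non-glycosylated form was never detected."""
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("occupancy"))
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "region_start", "region_end", "peptide", "tn_max",
             "glyco_ratio", "sd", "xtn_percent", "xtn_raw", "high_flag",
             "n_replicates", "partial_detection"]
        )
        for r in records:
            writer.writerow(
                [r.accession, r.region_start, r.region_end, r.peptide, r.tn_max,
                 "High" if r.high_flag else repr(r.glyco_ratio),
                 "" if r.sd is None else repr(r.sd),
                 ";".join(str(v) for v in r.xtn_percent),
                 ";".join(repr(v) for v in r.xtn_raw),
                 int(r.high_flag), r.n_replicates, int(r.partial_detection)]
            )


def format_occupancy_report(records: Iterable[OccupancyRecord]) -> str:
    """Human-readable occupancy report with bracket-coordinate peptides,
    e.g. ``[33]EAEVTLEAGGAEQEPGQALGK[53]``."""
    buf = io.StringIO()
    buf.write("accession\tpeptide\ttn_max\tglyco_ratio\txtn_percent\n")
    for r in records:
        ratio = "High" if r.high_flag else (
            f"{r.glyco_ratio:.2f} ± {r.sd:.2f}" if r.sd is not None
            else f"{r.glyco_ratio:.2f}"
        )
        buf.write(
            f"{r.accession}\t[{r.region_start}]{r.peptide}[{r.region_end}]\t"
            f"{r.tn_max}\t{ratio}\t"
            f"{'/'.join(str(v) for v in r.xtn_percent)}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Quant tables (rows x condition:replicate channels)


def write_quant_table(path: PathLike, table, index_name: str = "accession") -> None:
    """Write a pandas quant table (e.g. the protein-abundance table)."""
    with open(path, "w", newline="") as fh:
        fh.write(_schema_line("quant"))
        # repr keeps doubles round-trip exact (default %g formatting does not)
        table.to_csv(fh, sep="\t", index_label=index_name, lineterminator="\n",
                     float_format=lambda v: repr(float(v)))


def read_quant_table(path: PathLike):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#", index_col=0,
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# Plain-text config (key = value)


def read_config(path: PathLike) -> dict[str, str]:
    """Parse a ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ValidationError(f"{path} line {lineno}: expected key = value")
            key, value = stripped.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config(path: PathLike, config: dict[str, object]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX}/config v1\n")
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")
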