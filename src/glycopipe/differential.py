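"""Differential site-level glycosylation between wild type and knockouts.

Quantities live in "quant tables": pandas DataFrames whose rows are sites
(MultiIndex accession/position) or proteins and whose columns are TMT
channels labeled ``condition:replicate``. The workflow follows standard
isobaric practice: total-intensity normalization, removal of sites on
proteins whose overall abundance changed, median-ratio fold changes, a
two-sided equal-variance t-test on log2 intensities, Benjamini-Hochberg FDR
control across the contrast, and threshold-based regulation calls. A site
down-regulated in exactly one knockout of the panel is flagged
isoform-specific.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GlycoPSM, ProteinRecord, RegulationCall, ValidationError
from .site_catalog import select_quant_psm, single_site_filter


def channel_condition(channel: str) -> str:
    """Condition part of a ``condition:replicate`` channel label."""
    if ":" not in channel:
        raise ValidationError(f"channel {channel!r} is not condition:replicate")
    return channel.split(":", 1)[0]


def condition_channels(columns: Iterable[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for c in columns:
        out.setdefault(channel_condition(c), []).append(c)
    return out


# ---------------------------------------------------------------------------
# Table construction


def build_site_table(
    psms: Sequence[GlycoPSM],
    proteome: Sequence[ProteinRecord],
    prob_cutoff: float = 95.0,
) -> tuple[pd.DataFrame, dict]:
    """Site-keyed quant table from single-glycan glycopeptides.

    Each single-site glycopeptide contributes one row keyed by its protein
    coordinate (the confidently localized position of the anchoring ETD PSM,
    or the first residue of the peptide's S/T/Y span when localization stayed
    ambiguous). Multi-site and mixed-evidence glycopeptides are returned
    separately as a peptide-keyed table.

    Returns ``(site_table, meta)`` where meta holds per-site status/peptide
    and the peptide-level table under ``meta["peptide_table"]``.
    """
    sequences = {p.accession: p.sequence for p in proteome}
    single, multi = single_site_filter(psms)

    rows: dict[tuple[str, int], dict[str, float]] = {}
    anchor_score: dict[tuple[str, int], float] = {}
    info: dict[tuple[str, int], dict] = {}
    for key, group in single.items():
        selection = select_quant_psm(group)
        if selection.excluded:
            continue
        etd = [p for p in group if p.frag_type == "ETD"]
        best = max(etd, key=lambda p: p.psm_score)
        localized = [
            best.pep_start + pos - 1
            for pos, prob in zip(best.site_positions, best.site_probabilities)
            if prob > prob_cutoff
        ]
        if localized:
            site_key = (best.accession, localized[0])
            status = "unambiguous"
        else:
            seq_positions = [
                best.pep_start + i
                for i, aa in enumerate(best.peptide)
                if aa in "STY"
            ]
            if not seq_positions:
                continue
            site_key = (best.accession, min(seq_positions))
            status = "ambiguous"
        if site_key in rows and best.psm_score <= anchor_score[site_key]:
            continue
        if best.accession not in sequences:
            raise ValidationError(f"unknown accession {best.accession!r}")
        rows[site_key] = {
            c: v for c, v in selection.psm.intensities.items() if v is not None
        }
        anchor_score[site_key] = best.psm_score
        info[site_key] = {"status": status, "peptide": best.peptide}

    site_table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if not site_table.empty:
        site_table.index = pd.MultiIndex.from_tuples(
            site_table.index, names=["accession", "position"]
        )

    pep_rows = {}
    for key, group in multi.items():
        selection = select_quant_psm(group)
        if selection.excluded:
            continue
        pep_rows[key] = {
            c: v for c, v in selection.psm.intensities.items() if v is not None
        }
    peptide_table = pd.DataFrame.from_dict(pep_rows, orient="index").sort_index()
    return site_table, {"sites": info, "peptide_table": peptide_table}


# ---------------------------------------------------------------------------
# Normalization


def normalize_total(table: pd.DataFrame) -> pd.DataFrame:
    """Total-intensity normalization.

    Every channel is scaled by one factor so that all channel totals equal
    the grand mean of the input channel totals; within-channel structure is
    untouched. Channels with zero total are an error.
    """
    if table.empty:
        return table.copy()
    totals = table.sum(axis=0, skipna=True)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValidationError(f"channels with zero total intensity: {bad}")
    factors = totals.mean() / totals
    return table * factors


# ---------------------------------------------------------------------------
# Testing


def _log2_ttest(ko: np.ndarray, wt: np.ndarray) -> float:
    """Two-sided equal-variance t-test on log2 intensities.

    Degenerate zero-variance groups (exact simulations) are resolved by the
    limit: identical means give p = 1, different means p = 0.
    """
    a, b = np.log2(ko), np.log2(wt)
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (5% FDR convention upstream)."""
    if len(p_values) == 0:
        return np.array([])
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def test_sites(
    site_table: pd.DataFrame,
    wt_label: str,
    ko_label: str,
    alpha: float = 0.05,
    down_fc: float = 0.5,
    up_fc: float = 2.0,
    use_raw_p: bool = False,
    protein_flags: Optional[dict[str, str]] = None,
) -> list[RegulationCall]:
    """Differential calls for one knockout-vs-wild-type contrast.

    Fold change is the ratio of replicate medians (KO/WT); significance is a
    two-sided equal-variance t-test on log2 intensities, BH-adjusted across
    all sites tested in the contrast. ``call`` is "down" when fold change <
    ``down_fc`` with adjusted p < alpha (raw p when ``use_raw_p``), "up"
    symmetrically above ``up_fc``, otherwise "unchanged". Sites with fewer
    than two usable replicates in either condition are reported "untested".
    """
    groups = condition_channels(site_table.columns)
    for label in (wt_label, ko_label):
        if label not in groups:
            raise ValidationError(f"no channels for condition {label!r}")
        if len(groups[label]) < 2:
            raise ValidationError(f"condition {label!r} has fewer than 2 replicates")
    protein_flags = protein_flags or {}

    tested: list[tuple[tuple[str, int], float, float]] = []
    untested: list[tuple[str, int]] = []
    ko_matrix = site_table[groups[ko_label]].to_numpy(dtype=float)
    wt_matrix = site_table[groups[wt_label]].to_numpy(dtype=float)
    for i, key in enumerate(site_table.index):
        ko_vals = ko_matrix[i][~np.isnan(ko_matrix[i])]
        wt_vals = wt_matrix[i][~np.isnan(wt_matrix[i])]
        if len(ko_vals) < 2 or len(wt_vals) < 2:
            untested.append(key)
            continue
        fc = float(np.median(ko_vals) / np.median(wt_vals))
        p = _log2_ttest(ko_vals, wt_vals)
        tested.append((key, fc, p))

    adjusted = benjamini_hochberg([p for _, _, p in tested])
    calls = []
    for (key, fc, p), p_adj in zip(tested, adjusted):
        p_eff = p if use_raw_p else p_adj
        if fc < down_fc and p_eff < alpha:
            verdict = "down"
        elif fc > up_fc and p_eff < alpha:
            verdict = "up"
        else:
            verdict = "unchanged"
        calls.append(
            RegulationCall(
                accession=key[0],
                position=key[1],
                knockout=ko_label,
                fold_change=fc,
                log2_fc=math.log2(fc) if fc > 0 else float("-inf"),
                p_raw=p,
                p_adj=float(p_adj),
                call=verdict,
                protein_flag=protein_flags.get(key[0], ""),
            )
        )
    for key in untested:
        calls.append(
            RegulationCall(
                accession=key[0],
                position=key[1],
                knockout=ko_label,
                fold_change=float("nan"),
                log2_fc=float("nan"),
                p_raw=float("nan"),
                p_adj=float("nan"),
                call="untested",
                protein_flag=protein_flags.get(key[0], ""),
            )
        )
    calls.sort(key=lambda c: (c.accession, c.position))
    return calls


# ---------------------------------------------------------------------------
# Protein-abundance correction


def changed_proteins(
    protein_table: pd.DataFrame,
    wt_label: str,
    ko_label: str,
    fc_bounds: tuple[float, float] = (0.5, 2.0),
    alpha: float = 0.05,
) -> set[str]:
    """Proteins whose overall abundance changed in a knockout contrast
    (median fold change outside ``fc_bounds`` with BH-adjusted p < alpha)."""
    groups = condition_channels(protein_table.columns)
    lo, hi = fc_bounds
    rows = []
    ko_matrix = protein_table[groups[ko_label]].to_numpy(dtype=float)
    wt_matrix = protein_table[groups[wt_label]].to_numpy(dtype=float)
    for i, accession in enumerate(protein_table.index):
        ko_vals = ko_matrix[i][~np.isnan(ko_matrix[i])]
        wt_vals = wt_matrix[i][~np.isnan(wt_matrix[i])]
        if len(ko_vals) < 2 or len(wt_vals) < 2:
            continue
        fc = float(np.median(ko_vals) / np.median(wt_vals))
        rows.append((accession, fc, _log2_ttest(ko_vals, wt_vals)))
    adjusted = benjamini_hochberg([p for _, _, p in rows])
    return {
        acc
        for (acc, fc, _), p_adj in zip(rows, adjusted)
        if (fc < lo or fc > hi) and p_adj < alpha
    }


def protein_abundance_filter(
    site_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    wt_label: str,
    ko_labels: Sequence[str],
    fc_bounds: tuple[float, float] = (0.5, 2.0),
    alpha: float = 0.05,
    contrast: Optional[str] = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Remove sites sitting on abundance-changed proteins.

    With ``contrast`` given, only that knockout's proteome comparison is
    applied; otherwise a site is dropped when its protein changed in *any*
    knockout (the global universe selection). Sites whose protein was never
    quantified in the proteome are retained and flagged
    ``protein-unquantified`` in the returned flags map.
    """
    labels = [contrast] if contrast else list(ko_labels)
    removed: set[str] = set()
    for ko in labels:
        removed |= changed_proteins(protein_table, wt_label, ko, fc_bounds, alpha)
    quantified = set(protein_table.index)
    flags = {
        acc: "protein-unquantified"
        for acc in site_table.index.get_level_values("accession").unique()
        if acc not in quantified
    }
    keep = [acc not in removed for acc in site_table.index.get_level_values("accession")]
    return site_table.loc[keep], flags


# ---------------------------------------------------------------------------
# Isoform specificity


def assign_isoform_specificity(
    calls: Iterable[RegulationCall],
) -> list[RegulationCall]:
    """Annotate a panel of per-knockout calls with isoform specificity.

    A site is isoform-specific when it is called down in exactly one knockout
    and not down in every other contrast of the panel; sites down in two or
    more knockouts are flagged shared.
    """
    calls = list(calls)
    down_by_site: dict[tuple[str, int], list[RegulationCall]] = {}
    for c in calls:
        if c.call == "down":
            down_by_site.setdefault(c.site_key, []).append(c)
    for site_calls in down_by_site.values():
        if len(site_calls) == 1:
            site_calls[0].isoform_specific = True
        else:
            for c in site_calls:
                c.shared = True
    return calls


def summarize_panel(calls: Sequence[RegulationCall]) -> dict:
    """Panel-wide counts: per-knockout up/down, isoform-specific totals."""
    per_ko: dict[str, dict[str, int]] = {}
    for c in calls:
        entry = per_ko.setdefault(
            c.knockout, {"down": 0, "up": 0, "down_specific": 0}
        )
        if c.call == "down":
            entry["down"] += 1
            if c.isoform_specific:
                entry["down_specific"] += 1
        elif c.call == "up":
            entry["up"] += 1
    sites = {c.site_key for c in calls}
    down_sites = {c.site_key for c in calls if c.call == "down"}
    up_sites = {c.site_key for c in calls if c.call == "up"}
    specific_sites = {c.site_key for c in calls if c.isoform_specific}
    return {
        "n_sites_tested": len(sites),
        "n_sites_down": len(down_sites),
        "n_sites_up": len(up_sites),
        "n_sites_isoform_specific": len(specific_sites),
        "per_knockout": per_ko,
    }
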