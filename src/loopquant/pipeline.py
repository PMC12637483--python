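"""End-to-end orchestration: simulate/load -> quant -> stats -> report.

A run is driven by one YAML/dict config and a seed, executes the stages in
fixed order, writes every intermediate table as CSV, and records a manifest
(config snapshot, seeds, per-stage row counts, output digests) sufficient to
reproduce the run byte-for-byte.

Config schema (YAML mapping)::

    seed: 1
    conditions:                  # simulate mode
      - label: dark
        simulation: {p_loop: 0.05, n_cells: 2000}
      - label: light
        simulation: {p_loop: 0.25, n_cells: 2000}
    inputs:                      # or: load mode (mutually exclusive)
      nuclei: nuclei.csv
      spots: spots.csv
    analysis: {ploidy: 2, min_area: 90, contact_threshold: 0.27}
    control_condition: dark
    bin_by: fraction_close
    n_bins: 4
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__, io, quant, stats
from .config import AnalysisConfig, SimulationConfig
from .synthetic import generate_fish_dataset


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    config: dict
    seed: int
    condition_seeds: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    complete: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _condition_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def _load_or_simulate(config: dict, seed: int, manifest: RunManifest
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    if "conditions" in config:
        nuclei_parts, spot_parts = [], []
        for idx, cond in enumerate(config["conditions"]):
            label = cond["label"]
            sim_kwargs = dict(cond.get("simulation", {}))
            sim_kwargs.setdefault("seed", _condition_seed(seed, idx))
            sim = SimulationConfig(**sim_kwargs)
            manifest.condition_seeds[label] = sim.seed
            nuc, spots, _ = generate_fish_dataset(sim, condition=label)
            prefix = f"{label}:"
            nuc = nuc.assign(nucleus_id=prefix + nuc["nucleus_id"].astype(str))
            spots = spots.assign(
                nucleus_id=prefix + spots["nucleus_id"].astype(str))
            nuclei_parts.append(nuc)
            spot_parts.append(spots)
        return (pd.concat(nuclei_parts, ignore_index=True),
                pd.concat(spot_parts, ignore_index=True))
    if "inputs" in config:
        nuclei = io.read_table(config["inputs"]["nuclei"])
        spots = io.read_table(config["inputs"]["spots"])
        for key in ("nuclei", "spots"):
            manifest.digests[f"input:{key}"] = io.file_digest(
                config["inputs"][key])
        return nuclei, spots
    raise PipelineError("load", "config needs either 'conditions' or 'inputs'")


def run(config: dict | str | Path, out_dir: str | Path,
        seed: Optional[int] = None) -> RunManifest:
    """Execute the full analysis; write CSVs, a report, and a manifest."""
    if not isinstance(config, dict):
        config = io.load_config_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    config = {**config, "seed": seed}
    manifest = RunManifest(config=config, seed=seed)
    analysis = AnalysisConfig(**config.get("analysis", {}))

    stage = "load"
    try:
        nuclei, spots = _load_or_simulate(config, seed, manifest)
        manifest.stage_counts["nuclei_in"] = len(nuclei)

        stage = "qc_filter"
        kept, qc_report = quant.qc_filter_nuclei(nuclei, analysis)
        manifest.stage_counts["nuclei_after_qc"] = len(kept)
        manifest.stage_counts["rejected_qc"] = qc_report.n_input - qc_report.n_kept

        stage = "ploidy_filter"
        kept, ploidy_report = quant.ploidy_filter(kept, spots, analysis)
        manifest.stage_counts["nuclei_after_ploidy"] = len(kept)
        manifest.stage_counts["rejected_ploidy"] = (
            ploidy_report.n_input - ploidy_report.n_kept)

        stage = "match"
        pairs = quant.match_all_nuclei(kept, spots, analysis)
        pairs = quant.attach_condition(pairs, kept)
        manifest.stage_counts["allele_pairs"] = len(pairs)

        stage = "summarize"
        rna = spots[spots["channel"] == "rna"]
        rna = rna[rna["nucleus_id"].isin(set(kept["nucleus_id"]))]
        cells = quant.summarize_cells(kept, pairs, rna)
        cells = quant.bin_cells(cells, by=config.get("bin_by", "fraction_close"),
                                n_bins=int(config.get("n_bins", analysis.n_bins)))
        manifest.stage_counts["cells"] = len(cells)

        stage = "stats"
        fractions = quant.condition_contact_fraction(pairs)
        medians = quant.median_pair_distance(pairs)
        stats_rows = []
        full = cells[cells["n_pairs"] == analysis.ploidy]
        for cond in fractions["condition"]:
            sub = full[full["condition"] == cond]
            if len(sub) == 0:
                continue
            dist = stats.observed_distribution(sub, analysis.ploidy)
            test = stats.independence_test(dist, fitted_params=1)
            null = stats.binomial_expected(dist.pooled_p_c, analysis.ploidy)
            row: dict[str, Any] = {
                "condition": cond, "n_cells": dist.total_cells,
                "p_c": dist.pooled_p_c, "chi2": test.statistic,
                "df": test.df, "pvalue": test.pvalue,
                "stars": stats.significance_stars(test.pvalue),
            }
            for c in range(analysis.ploidy + 1):
                row[f"observed_{c}"] = int(dist.counts[c])
                row[f"expected_{c}"] = float(
                    null.expected_fractions[c] * dist.total_cells)
            stats_rows.append(row)
        stats_table = pd.DataFrame(stats_rows)
        ok = fractions["n_alleles"] >= 1
        mar = (
            stats.marascuilo(stats.ProportionSet(
                labels=list(fractions.loc[ok, "condition"]),
                proportions=fractions.loc[ok, "fraction"].to_numpy(),
                sizes=fractions.loc[ok, "n_alleles"].to_numpy(),
            ))
            if ok.sum() >= 2 else pd.DataFrame()
        )

        stage = "write"
        tables = {
            "nuclei": kept, "spots": spots, "pairs": pairs, "cells": cells,
            "contact_fractions": fractions, "median_distances": medians,
            "independence_tests": stats_table, "marascuilo": mar,
        }
        for name, df in tables.items():
            path = io.write_table(df, out / f"{name}.csv")
            manifest.outputs[name] = str(path)
            manifest.digests[name] = io.file_digest(path)

        stage = "report"
        text = report(tables, analysis,
                      control=config.get("control_condition"))
        (out / "report.txt").write_text(text)
        manifest.outputs["report"] = str(out / "report.txt")
        manifest.complete = True
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    finally:
        (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def report(tables: dict[str, pd.DataFrame], analysis: AnalysisConfig,
           control: Optional[str] = None) -> str:
    """Render the human-readable summary of a run's output tables."""
    lines: list[str] = ["# loopquant run report", ""]

    lines.append("## Contact fractions per condition "
                 f"(distance < {analysis.contact_threshold} um)")
    fr = tables.get("contact_fractions", pd.DataFrame())
    if len(fr) == 0:
        lines.append("  (no data)")
    else:
        for _, r in fr.iterrows():
            if r["n_alleles"] == 0 or not np.isfinite(r["fraction"]):
                lines.append(f"  {r['condition']}: no data")
            else:
                lines.append(
                    f"  {r['condition']}: {r['fraction']:.4f} "
                    f"({int(r['n_contacts'])}/{int(r['n_alleles'])} alleles)")
    lines.append("")

    lines.append("## Median allele-pair distances (um)")
    med = tables.get("median_distances", pd.DataFrame())
    if len(med) == 0:
        lines.append("  (no data)")
    else:
        for _, r in med.iterrows():
            lines.append(f"  {r['condition']}: {r['median_um']:.4f} "
                         f"(n={int(r['n_alleles'])})")
    lines.append("")

    lines.append("## RNA transcription-site metrics by contact-fraction bin")
    cells = tables.get("cells", pd.DataFrame())
    bin_col = "fraction_close_bin"
    if len(cells) == 0 or bin_col not in cells.columns:
        lines.append("  (no data)")
    else:
        norm = 1.0
        if control is not None:
            ctrl = cells[cells["condition"] == control]
            if len(ctrl) == 0:
                raise PipelineError(
                    "report", f"control_condition {control!r} not present")
            ref = ctrl["rna_total_intensity"].mean()
            norm = ref if np.isfinite(ref) and ref > 0 else 1.0
        grouped = cells.dropna(subset=[bin_col]).groupby(
            ["condition", bin_col], observed=True)
        for (cond, b), sub in grouped:
            lines.append(
                f"  {cond} bin {b}: mean TS count {sub['rna_spot_count'].mean():.3f}, "
                f"rel. RNA intensity {sub['rna_total_intensity'].mean() / norm:.3f} "
                f"(n={len(sub)})")
    lines.append("")

    lines.append("## Observed vs expected close-allele distributions")
    st = tables.get("independence_tests", pd.DataFrame())
    if len(st) == 0:
        lines.append("  (no data)")
    else:
        for _, r in st.iterrows():
            obs = [int(r[f"observed_{c}"]) for c in range(analysis.ploidy + 1)]
            exp = [r[f"expected_{c}"] for c in range(analysis.ploidy + 1)]
            lines.append(
                f"  {r['condition']}: p_c={r['p_c']:.4f}, observed {obs}, "
                f"expected {[f'{e:.1f}' for e in exp]}, "
                f"chi2={r['chi2']:.3f} (df={int(r['df'])}), "
                f"p={r['pvalue']:.3g} {r['stars']}")
    lines.append("")

    lines.append("## Pairwise contact-fraction comparisons (Marascuilo)")
    mar = tables.get("marascuilo", pd.DataFrame())
    if len(mar) == 0:
        lines.append("  (no data)")
    else:
        for _, r in mar.iterrows():
            flag = "significant" if r["significant"] else "n.s."
            lines.append(
                f"  {r['group_i']} vs {r['group_j']}: |diff|={r['diff']:.4f}, "
                f"critical range={r['critical_range']:.4f} -> {flag}")
    lines.append("")
    return "\n".join(lines)
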