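"""End-to-end orchestration: simulate -> connectome -> SCF -> statistics.

A run is fully determined by its configuration and seed; every numeric
table is written to disk and re-running with the same inputs reproduces
the bundle byte-identically.  Intermediate counts (dropped streamlines,
undefined regions, tests run) are surfaced in the manifest because they
encode the association-fiber exclusion rules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjacency import read_matrix_tsv, write_matrix_tsv
from .connectome import ConnectivityMatrix, Tractogram, connectivity_from_tractogram
from .scf import SCFResult, group_rscf_atlas, relative_difference, scf_result
from .stats import PairedComparison, compare_gscf, compare_rscf, top10_frequency
from .synthetic import CohortSpec, make_connectome_ensemble


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    mode: str = "simulate"  # "simulate" | "from-files"
    cohort: dict = field(default_factory=dict)
    input_manifest: str | None = None  # from-files mode
    fdr_level: float = 0.05
    include_intra: bool = False
    length_threshold_mm: float | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "from-files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate":
            if self.seed is None:
                raise ValueError("seed is mandatory in simulate mode")
            CohortSpec(seed=self.seed, **self.cohort)  # validate eagerly
        if self.mode == "from-files" and not self.input_manifest:
            raise ValueError("from-files mode requires input_manifest")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultsBundle:
    """All tables of one run plus a provenance manifest."""

    gscf_table: pd.DataFrame  # subject x condition
    rscf_tables: dict[str, pd.DataFrame]  # condition -> subject x region
    gscf_comparisons: list[PairedComparison]
    rscf_comparisons: list[PairedComparison]
    rscf_report: pd.DataFrame
    top10_table: pd.DataFrame
    homologous_table: pd.DataFrame
    atlas_table: pd.DataFrame
    manifest: dict


def comparisons_to_frame(comparisons: list[PairedComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def _load_from_files(manifest_path: str):
    with open(manifest_path) as fh:
        man = json.load(fh)
    base = Path(manifest_path).parent
    regions = pd.read_csv(base / man["regions"], sep="\t")
    adjacency = read_matrix_tsv(base / man["adjacency"])
    ensemble = {}
    conditions = man["conditions"]
    for entry in man["matrices"]:
        path = base / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"matrix listed in manifest missing: {path}")
        ensemble[(int(entry["subject"]), entry["condition"])] = read_matrix_tsv(path)
    return ensemble, regions, adjacency, conditions


def run_experiment(config: RunConfig, out_dir) -> ResultsBundle:
    """Execute the full pipeline and write the results bundle to ``out_dir``."""
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        spec = CohortSpec(seed=config.seed, **config.cohort)
        ensemble, truth = make_connectome_ensemble(spec)
        regions, adjacency = truth.regions, truth.true_adjacency
        conditions = list(spec.resolutions)
    else:
        ensemble, regions, adjacency, conditions = _load_from_files(config.input_manifest)

    subjects = sorted({s for s, _ in ensemble})
    results: dict[tuple[int, str], SCFResult] = {}
    for (s, r), w in ensemble.items():
        cm = ConnectivityMatrix(
            w, include_intra=config.include_intra,
            length_threshold_mm=config.length_threshold_mm,
        )
        results[(s, r)] = scf_result(cm, adjacency)

    gscf_table = pd.DataFrame(
        {r: [results[(s, r)].gscf for s in subjects] for r in conditions},
        index=pd.Index(subjects, name="subject"),
    )
    rscf_tables = {
        r: pd.DataFrame(
            {s: results[(s, r)].rscf for s in subjects}
        ).T.rename_axis("subject")
        for r in conditions
    }

    gscf_comp = compare_gscf(gscf_table, conditions, fdr_level=config.fdr_level)
    high, low = conditions[0], conditions[-1]
    rscf_comp, rscf_report = compare_rscf(
        rscf_tables[high], rscf_tables[low], regions, fdr_level=config.fdr_level
    )
    diffs = pd.DataFrame(
        [{int(c.label): c.mean_relative_difference_pct for c in rscf_comp}],
        index=["simulated" if config.mode == "simulate" else "from-files"],
    )
    top10, homologous = top10_frequency(diffs, regions)

    atlas = group_rscf_atlas([results[(s, high)] for s in subjects])
    atlas_table = pd.DataFrame(
        {
            "region": atlas.mean.index,
            "name": regions.set_index("id").loc[atlas.mean.index, "name"].to_numpy(),
            "hemisphere": regions.set_index("id").loc[atlas.mean.index, "hemisphere"].to_numpy(),
            "rscf_mean": atlas.mean.to_numpy(),
            "rscf_sd": atlas.sd.to_numpy(),
            "n_defined": atlas.n_defined.to_numpy(),
        }
    )

    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "conditions": conditions,
        "n_subjects": len(subjects),
        "n_regions": len(regions),
        "counters": {
            "tests_run": len(gscf_comp) + len(rscf_comp),
            "undefined_region_entries": int(
                sum(len(res.undefined_regions) for res in results.values())
            ),
            "regions_excluded_from_rscf": int((~rscf_report["tested"]).sum()),
        },
        "files": [],
    }

    _write_tsv(gscf_table, tables / "gscf.tsv")
    for r in conditions:
        _write_tsv(rscf_tables[r], tables / f"rscf_{r}.tsv")
    _write_tsv(comparisons_to_frame(gscf_comp), tables / "gscf_comparisons.tsv", index=False)
    _write_tsv(comparisons_to_frame(rscf_comp), tables / "rscf_comparisons.tsv", index=False)
    _write_tsv(rscf_report, tables / "rscf_report.tsv", index=False)
    _write_tsv(top10, tables / "top10.tsv", index=False)
    _write_tsv(homologous, tables / "top10_homologous.tsv", index=False)
    _write_tsv(atlas_table, tables / "atlas.tsv", index=False)
    manifest["files"] = sorted(p.name for p in tables.glob("*.tsv"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ResultsBundle(
        gscf_table=gscf_table,
        rscf_tables=rscf_tables,
        gscf_comparisons=gscf_comp,
        rscf_comparisons=rscf_comp,
        rscf_report=rscf_report,
        top10_table=top10,
        homologous_table=homologous,
        atlas_table=atlas_table,
        manifest=manifest,
    )


def write_ensemble(ensemble, regions, adjacency, conditions, out_dir) -> Path:
    """Persist a simulated ensemble as TSV matrices plus a JSON manifest,
    readable back through from-files mode."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions.to_csv(out / "regions.tsv", sep="\t", index=False)
    write_matrix_tsv(adjacency, out / "adjacency.tsv")
    entries = []
    for (s, r), w in sorted(ensemble.items()):
        name = f"w_sub{s:03d}_{r}.tsv"
        write_matrix_tsv(w, out / name)
        entries.append({"subject": s, "condition": r, "path": name})
    manifest = {
        "regions": "regions.tsv",
        "adjacency": "adjacency.tsv",
        "conditions": list(conditions),
        "matrices": entries,
    }
    path = out / "input_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def variant_sweep(
    tractogram: Tractogram,
    parcellation,
    adjacency: pd.DataFrame,
    variants: list[tuple[bool, float | None]],
    search_radius_mm: float = 2.0,
) -> pd.DataFrame:
    """Recompute SCF under alternative short-range-fiber definitions.

    Each variant is ``(include_intra, length_threshold_mm)``; the base
    definition is ``(False, None)``.  Returns one row per variant with the
    global fraction and its difference from the base, plus a sign-agreement
    flag for the cross-variant consistency report.
    """
    base = scf_result(
        connectivity_from_tractogram(tractogram, parcellation, search_radius_mm), adjacency
    )
    rows = [
        {
            "include_intra": False,
            "length_threshold_mm": math.inf,
            "gscf": base.gscf,
            "delta_vs_base_pct": 0.0,
        }
    ]
    for include_intra, thr in variants:
        cm = connectivity_from_tractogram(
            tractogram, parcellation, search_radius_mm,
            include_intra=include_intra, length_threshold_mm=thr,
        )
        res = scf_result(cm, adjacency)
        rows.append(
            {
                "include_intra": include_intra,
                "length_threshold_mm": math.inf if thr is None else thr,
                "gscf": res.gscf,
                "delta_vs_base_pct": relative_difference(res.gscf, base.gscf),
            }
        )
    return pd.DataFrame(rows)
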