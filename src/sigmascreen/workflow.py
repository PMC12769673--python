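"""Pipeline orchestration: configuration, seeds, manifests, end-to-end runs.

``run_screen_pipeline`` ties simulator -> (optional FASTQ -> quantification)
-> sigma scoring -> hit calling -> gene-set enrichment, writing TSV/JSON
outputs plus a manifest with a checksum for every file.  Identical config +
master seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import enrichment as enr
from . import scoring, simulate, tracing
from .library import GuideLibrary

logger = logging.getLogger(__name__)

DEFAULT_SCREEN_CONFIG: dict = {
    "screen": {
        "n_genes": 1000,
        "guides_per_gene": 4,
        "n_controls": 100,
        "design": {},  # ScreenDesign keyword overrides
        "fitness": {
            "class_spec": {
                "ACT": {
                    "n_suppressors": 50,
                    "n_sick": 50,
                    "s_suppressor": 0.4,
                    "s_sick": -0.4,
                }
            },
            "shared_sick_genes": 20,
            "s_shared_sick": -0.4,
        },
    },
    "scoring": {
        "contrasts": [["ACT", "ETOH"], ["ACT", "ACTCAP"]],
        "threshold": 3.0,
        "pseudocount": 0.5,
        "normalization": "total",
        "z_before_average": False,
    },
    "enrichment": {"gene_sets": None, "min_set_size": 3},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULT_SCREEN_CONFIG``)."""

    raw: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_SCREEN_CONFIG)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        merged = json.loads(json.dumps(DEFAULT_SCREEN_CONFIG))
        for section, value in data.items():
            if isinstance(value, dict) and isinstance(merged.get(section), dict):
                merged[section].update(value)
            else:
                merged[section] = value
        return cls(merged)

    def design(self) -> simulate.ScreenDesign:
        kwargs = dict(self.raw["screen"].get("design") or {})
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        return simulate.ScreenDesign(**kwargs)

    def validate(self) -> None:
        design = self.design()
        for a, b in self.raw["scoring"]["contrasts"]:
            for cond in (a, b):
                if cond not in design.conditions:
                    raise ValueError(
                        f"contrast references undeclared condition {cond!r}"
                    )
        sets_path = self.raw["enrichment"].get("gene_sets")
        if sets_path is not None and not Path(sets_path).exists():
            raise ValueError(f"gene-set file does not exist: {sets_path}")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, payload: dict) -> None:
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    payload["files"] = {
        str(p.relative_to(out_dir)): _sha256(p) for p in files
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_screen_pipeline(
    config: PipelineConfig | dict | None = None,
    seed: int = 0,
    out_dir="screen_run",
) -> dict:
    """Simulate, score, call hits and (optionally) enrich; write outputs.

    On stage failure, partial outputs are removed and the failing stage is
    named.  Returns the manifest dictionary.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    config.validate()

    out = Path(out_dir)
    tmp = out.parent / (out.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    stage = "setup"
    try:
        scr = config.raw["screen"]
        fit = scr.get("fitness") or {}
        design = config.design()

        stage = "simulate"
        library, truth, traj, table = simulate.simulate_screen(
            n_genes=scr["n_genes"],
            guides_per_gene=scr["guides_per_gene"],
            n_controls=scr["n_controls"],
            design=design,
            class_spec=fit.get("class_spec"),
            shared_sick_genes=fit.get("shared_sick_genes", 0),
            s_shared_sick=fit.get("s_shared_sick"),
            seed=seed,
        )
        library.to_tsv(tmp / "library.tsv")
        truth.to_json(tmp / "truth.json")
        traj.growth.to_csv(tmp / "growth.tsv", sep="\t", index=False, float_format="%.10g")
        table.to_tsv(tmp / "counts.tsv", tmp / "samples.tsv", tmp / "sample_stats.tsv")

        stage = "score"
        sc = config.raw["scoring"]
        contrasts = [tuple(c) for c in sc["contrasts"]]
        scores = scoring.score_screen(
            table,
            library,
            contrasts=contrasts,
            pseudocount=sc["pseudocount"],
            normalization=sc["normalization"],
            z_before_average=sc["z_before_average"],
            threshold=sc["threshold"],
        )
        scores.mean_lfc.rename_axis("gene").to_csv(
            tmp / "gene_lfc.tsv", sep="\t", float_format="%.10g"
        )
        scores.z.rename_axis("gene").to_csv(
            tmp / "gene_z.tsv", sep="\t", float_format="%.10g"
        )
        for (a, b) in contrasts:
            tag = f"{a}_vs_{b}"
            scoring.export_sigma_table(
                scores.z, a, b, tmp / f"sigma_{tag}.tsv", threshold=sc["threshold"]
            )
            scores.hits[(a, b)].to_csv(
                tmp / f"hits_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
            )

        stage = "enrich"
        en = config.raw["enrichment"]
        if en.get("gene_sets"):
            sets = enr.read_gmt(en["gene_sets"])
            universe = list(scores.z.index)
            for (a, b) in contrasts:
                tag = f"{a}_vs_{b}"
                hits = scores.hits[(a, b)]
                sup = hits.loc[hits["direction"] == "suppressor", "gene"].tolist()
                result = enr.enrich_sets(
                    sup, universe, sets, min_set_size=en.get("min_set_size", 3)
                )
                result.to_csv(
                    tmp / f"enrichment_{tag}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.raw,
            "config_hash": config.hash(),
            "master_seed": int(seed),
            "record_counts": {
                "guides": int(library.n_guides),
                "genes": len(library.genes),
                "samples": len(table.sample_names),
                "conditions": len(design.conditions),
                "replicates": int(design.n_replicates),
            },
        }
        _write_manifest(tmp, manifest)
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise RuntimeError(f"screen pipeline failed at stage {stage!r}: {exc}") from exc

    if out.exists():
        shutil.rmtree(out)
    tmp.rename(out)
    with open(out / "manifest.json") as fh:
        return json.load(fh)


def run_tracing_pipeline(
    mid_csv=None,
    f_ppp_grid: list[float] | None = None,
    tracer: tracing.TracerSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    out_dir="tracing_run",
    min_fraction_of_median: float = 0.2,
) -> dict:
    """Correction -> normalization -> ratio tables, with QC exclusions.

    Either reads a MID CSV (columns sample, metabolite, m0..mN) or forward-
    simulates one sample per value of ``f_ppp_grid``.
    """
    import pandas as pd

    tracer = tracer or tracing.TracerSpec()
    out = Path(out_dir)
    tmp = out.parent / (out.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    stage = "input"
    try:
        if mid_csv is not None:
            mids = tracing.read_mid_csv(mid_csv)
        elif f_ppp_grid:
            ss = np.random.SeedSequence(seed)
            mids = {}
            for f, child in zip(f_ppp_grid, ss.spawn(len(f_ppp_grid))):
                sample_seed = int(child.generate_state(1)[0] % (2**31))
                mids[f"fppp_{f:.2f}"] = tracing.simulate_labeling(
                    tracing.FluxScenario(f_ppp=f), tracer,
                    noise_sd=noise_sd, seed=sample_seed,
                )
            tracing.write_mid_csv(mids, tmp / "simulated_mids.csv")
        else:
            raise ValueError("either mid_csv or f_ppp_grid is required")

        stage = "qc"
        totals = {
            s: sum(m.total for m in ms.values()) for s, ms in mids.items()
        }
        kept, excluded = tracing.flag_low_yield(totals, min_fraction_of_median)

        stage = "correct"
        rows = []
        for sample in kept:
            sample_mids = mids[sample]
            _, pool_totals = tracing.normalize_total(sample_mids)
            for name, mid in sorted(sample_mids.items()):
                M = tracing.correction_matrix(mid.n_carbons, tracer.p13, tracer.purity)
                corrected, residual = tracing.correct_mid(mid, M)
                row = {
                    "sample": sample,
                    "metabolite": name,
                    "total_intensity": pool_totals[name],
                    "residual": residual,
                }
                for i, frac in enumerate(corrected.fractions()):
                    row[f"m{i}"] = frac
                if name == "lactate":
                    row["ppp_index"] = tracing.ppp_index(corrected)
                    row["ppp_fraction"] = tracing.ppp_fraction(corrected)
                rows.append(row)
        corrected_frame = pd.DataFrame(rows)
        corrected_frame.to_csv(
            tmp / "corrected_mids.csv", index=False, float_format="%.12g"
        )

        stage = "ratios"
        ratio_rows = []
        for sample in kept:
            sample_mids = mids[sample]
            row = {"sample": sample}
            if "lactate" in sample_mids:
                M = tracing.correction_matrix(3, tracer.p13, tracer.purity)
                lac, _ = tracing.correct_mid(sample_mids["lactate"], M)
                row["lactate_m1_m2_ratio"] = tracing.ppp_index(lac)
                row["ppp_fraction"] = tracing.ppp_fraction(lac)
            if "g6p" in sample_mids and "glucose" in sample_mids:
                row["uptake_index"] = tracing.uptake_index(
                    sample_mids["g6p"].total, sample_mids["glucose"].total
                )
            ratio_rows.append(row)
        pd.DataFrame(ratio_rows).to_csv(
            tmp / "ratios.csv", index=False, float_format="%.12g"
        )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "master_seed": int(seed),
            "tracer": {"purity": tracer.purity, "p13": tracer.p13},
            "noise_sd": noise_sd,
            "samples_kept": kept,
            "samples_excluded": excluded,
        }
        _write_manifest(tmp, manifest)
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise RuntimeError(f"tracing pipeline failed at stage {stage!r}: {exc}") from exc

    if out.exists():
        shutil.rmtree(out)
    tmp.rename(out)
    with open(out / "manifest.json") as fh:
        return json.load(fh)
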