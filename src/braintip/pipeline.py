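"""Stage orchestration: validated config, seeded runs, manifests.

Stages run in dependency order: simulate -> qc -> de -> deswan -> score ->
noise -> dnb -> report. Each stage writes its artifacts plus a manifest
entry (stage, parameters, seed, input hashes, timing) so that identical
config + seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import deswan, diffexp, dnb, genescore, noise, qc, synthetic

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "qc", "de", "deswan", "score", "noise", "dnb", "report")

_KNOWN_KEYS = {
    "input_path", "out_dir", "seed", "log_level",
    "simulate", "qc", "de", "deswan", "score", "noise", "dnb",
}
_SIMULATE_KEYS = {
    "n_genes", "donors_per_age", "cells_per_donor", "age_grid",
    "wave_centers", "wave_genes_per_center", "wave_log2_effect", "wave_steepness",
    "transition_interval", "transition_module_size", "sd_inflation",
    "rho_in_state", "rho_baseline",
}
_QC_KEYS = {"min_features", "max_features", "max_mito_fraction", "target_scale"}
_DE_KEYS = {"fc_threshold", "alpha", "min_pct"}
_DESWAN_KEYS = {"window_width", "alpha", "min_group"}
_SCORE_KEYS = {"set_size", "top_fraction", "quantile_q"}
_NOISE_KEYS = {"n_bins", "genes_per_bin", "target_depth"}
_DNB_KEYS = {"mode", "min_module_size", "cut_height"}


class ConfigError(ValueError):
    """Raised when the run configuration fails validation (exit code 2)."""


class DataError(ValueError):
    """Raised when required inputs are missing or inconsistent (exit code 3)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration with paper-default stage parameters."""

    raw: dict[str, Any] = field(default_factory=dict)
    out_dir: Path = Path("braintip_out")
    seed: int = 0
    input_path: Path | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in [
            ("simulate", _SIMULATE_KEYS), ("qc", _QC_KEYS), ("de", _DE_KEYS),
            ("deswan", _DESWAN_KEYS), ("score", _SCORE_KEYS),
            ("noise", _NOISE_KEYS), ("dnb", _DNB_KEYS),
        ]:
            extra = set(d.get(section, {}) or {}) - allowed
            if extra:
                raise ConfigError(f"unknown keys in {section!r}: {sorted(extra)}")
        cfg = cls(
            raw=d,
            out_dir=Path(d.get("out_dir", "braintip_out")),
            seed=int(d.get("seed", 0)),
            input_path=Path(d["input_path"]) if d.get("input_path") else None,
        )
        cfg.qc_config()  # validate eagerly (raises on e.g. min > max)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def section(self, name: str) -> dict[str, Any]:
        return dict(self.raw.get(name, {}) or {})

    def qc_config(self) -> qc.QCConfig:
        try:
            return qc.QCConfig(**self.section("qc"))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid qc section: {exc}") from exc


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages in dependency order; returns the out dir."""
    requested = list(stages) if stages else list(STAGE_ORDER)
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    requested = [s for s in STAGE_ORDER if s in requested]
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: list[dict[str, Any]] = []
    seed = config.seed

    cohort_dir = out / "cohort"
    state: dict[str, Any] = {}

    def record(stage: str, params: dict[str, Any], artifacts: list[Path], t0: float) -> None:
        manifest.append(
            {
                "stage": stage,
                "seed": seed,
                "parameters": params,
                "artifacts": {str(p.relative_to(out)): _hash_file(p) for p in artifacts},
                "elapsed_s": round(time.monotonic() - t0, 3),
            }
        )

    def load_cohort() -> None:
        if "counts" in state:
            return
        src = cohort_dir if cohort_dir.exists() else config.input_path
        if src is None or not Path(src).exists():
            raise DataError("no cohort found: run the 'simulate' stage first or set input_path")
        counts, meta = synthetic.read_cohort(src)
        state["counts"], state["meta"] = counts, meta

    def require_norm() -> None:
        if "norm" not in state:
            raise DataError("normalized expression missing: run the 'qc' stage first")

    for stage in requested:
        t0 = time.monotonic()
        if stage == "simulate":
            p = config.section("simulate")
            spec = synthetic.CohortSpec(
                age_grid=tuple(p.get("age_grid", synthetic.DEFAULT_AGE_GRID)),
                donors_per_age=int(p.get("donors_per_age", 1)),
                cells_per_donor=int(p.get("cells_per_donor", 200)),
                n_genes=int(p.get("n_genes", 2000)),
                seed=seed,
            )
            waves = []
            n_wave = int(p.get("wave_genes_per_center", 300))
            gene_cursor = spec.n_mito
            for c in p.get("wave_centers", []):
                waves.append(
                    synthetic.WaveSpec(
                        center_age=float(c),
                        gene_ids=frozenset(range(gene_cursor, gene_cursor + n_wave)),
                        log2_effect=float(p.get("wave_log2_effect", 1.0)),
                        steepness=float(p.get("wave_steepness", 0.5)),
                    )
                )
                gene_cursor += n_wave
            transition = None
            if p.get("transition_interval"):
                size = int(p.get("transition_module_size", 20))
                transition = synthetic.TransitionSpec(
                    state_interval=tuple(p["transition_interval"]),
                    module_gene_ids=frozenset(range(gene_cursor, gene_cursor + size)),
                    sd_inflation=float(p.get("sd_inflation", 3.0)),
                    rho_in_state=float(p.get("rho_in_state", 0.7)),
                    rho_baseline=float(p.get("rho_baseline", 0.2)),
                )
            counts, meta, truth = synthetic.generate_cohort(spec, waves, transition)
            synthetic.write_cohort(counts, meta, cohort_dir, truth)
            state["counts"], state["meta"], state["truth"] = counts, meta, truth
            record(stage, p, sorted(cohort_dir.glob("*")), t0)

        elif stage == "qc":
            load_cohort()
            cfg = config.qc_config()
            counts, meta, report = qc.filter_nuclei(state["counts"], state["meta"], cfg)
            meta = qc.assign_age_groups(meta)
            norm = qc.normalize_log(counts, cfg)
            state.update(counts=counts, meta=meta, norm=norm)
            report.to_json(out / "qc_report.json")
            record(stage, config.section("qc"), [out / "qc_report.json"], t0)

        elif stage == "de":
            require_norm()
            p = config.section("de")
            meta = state["meta"]
            labels = np.where(meta["age_group"] == "old", "A",
                              np.where(meta["age_group"] == "young", "B", "-"))
            keep = labels != "-"
            table = diffexp.rank_sum_de(
                state["norm"][:, np.flatnonzero(keep)],
                labels[keep],
                fc_threshold=float(p.get("fc_threshold", 1.2)),
                alpha=float(p.get("alpha", 0.05)),
                min_pct=float(p.get("min_pct", 0.1)),
                gene_ids=state["counts"].gene_ids,
            )
            table.to_csv(out / "de_old_vs_young.tsv", sep="\t")
            record(stage, p, [out / "de_old_vs_young.tsv"], t0)

        elif stage == "deswan":
            require_norm()
            p = config.section("deswan")
            unit, donor_meta = deswan.pseudobulk(state["norm"], state["meta"])
            cfg = deswan.SwanConfig(
                window_width=float(p.get("window_width", 20.0)),
                alpha=float(p.get("alpha", 0.05)),
                min_group=int(p.get("min_group", 3)),
            )
            profile = deswan.deswan_profile(unit, donor_meta["age"], cfg)
            peaks = deswan.find_peaks(profile)
            profile.to_csv(out / "deswan_profile.tsv", sep="\t", index=False)
            with open(out / "deswan_peaks.json", "w", encoding="utf-8") as fh:
                json.dump([{"center": c, "height": h} for c, h in peaks], fh, indent=1)
            state["profile"] = profile
            record(stage, p, [out / "deswan_profile.tsv", out / "deswan_peaks.json"], t0)

        elif stage == "score":
            require_norm()
            p = config.section("score")
            rng = np.random.default_rng(seed + 1)
            size = int(p.get("set_size", 50))
            set_idx = rng.choice(state["counts"].n_genes, size=size, replace=False)
            scores = genescore.auc_score(
                state["norm"], np.sort(set_idx),
                top_fraction=float(p.get("top_fraction", 0.05)),
            )
            meta = state["meta"]
            delta = genescore.threshold_shift_score(
                scores, meta["age_group"], quantile_q=float(p.get("quantile_q", 0.90))
            )
            enr = genescore.enrichment_table(meta)
            pd.DataFrame({"cell_id": meta["cell_id"], "score": scores}).to_csv(
                out / "set_scores.tsv", sep="\t", index=False
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            with open(out / "threshold_shift.json", "w", encoding="utf-8") as fh:
                json.dump({"delta": delta}, fh)
            record(stage, p, [out / "set_scores.tsv", out / "enrichment.tsv",
                              out / "threshold_shift.json"], t0)

        elif stage == "noise":
            load_cohort()
            p = config.section("noise")
            cfg = noise.NoiseConfig(
                n_bins=int(p.get("n_bins", 10)),
                genes_per_bin=int(p.get("genes_per_bin", 10)),
                target_depth=p.get("target_depth"),
                seed=seed,
            )
            counts = state["counts"].values
            depth = np.asarray(counts.sum(axis=0)).ravel()
            target = cfg.target_depth or int(depth[depth > 0].min())
            down = noise.downsample_counts(counts, target, seed=seed)
            norm_down = qc.normalize_log(down, config.qc_config())
            inv = noise.select_invariant_genes(norm_down, cfg)
            meta = state["meta"]
            if "age_group" not in meta.columns:
                meta = qc.assign_age_groups(meta)
            dist = noise.noise_distance(norm_down, meta, inv)
            dist["age_group"] = meta["age_group"].to_numpy()
            comp = noise.compare_noise(dist, meta["age_group"].to_numpy())
            dist.to_csv(out / "noise_distances.tsv", sep="\t", index=False)
            comp.to_csv(out / "noise_comparison.tsv", sep="\t", index=False)
            record(stage, p, [out / "noise_distances.tsv", out / "noise_comparison.tsv"], t0)

        elif stage == "dnb":
            require_norm()
            p = config.section("dnb")
            meta = state["meta"]
            states = dnb.bin_states(meta, mode=p.get("mode", "age"))
            scores = dnb.score_states(
                state["norm"], states,
                min_module_size=int(p.get("min_module_size", 10)),
                cut_height=float(p.get("cut_height", 0.75)),
            )
            report = dnb.locate_tipping_point(scores, states, meta)
            report.to_json(out / "tipping_report.json", gene_ids=state["counts"].gene_ids)
            report.labels.to_csv(out / "dnb_labels.tsv", sep="\t", index=False)
            tip_state = next(s for s in states.states if s.state_id == report.tipping_state)
            sub = state["norm"][:, np.asarray(tip_state.cell_index, int)].toarray()
            edges = dnb.export_network(
                sub, report.scores[report.tipping_state].module,
                gene_ids=state["counts"].gene_ids,
            )
            edges.to_csv(out / "dnb_network.tsv", sep="\t", index=False)
            record(stage, p, [out / "tipping_report.json", out / "dnb_labels.tsv",
                              out / "dnb_network.tsv"], t0)

        elif stage == "report":
            existing = sorted(
                str(p.relative_to(out)) for p in out.rglob("*")
                if p.is_file() and p.name != "report.json"
            )
            with open(out / "report.json", "w", encoding="utf-8") as fh:
                json.dump({"seed": seed, "artifacts": existing}, fh, indent=1)
            record(stage, {}, [out / "report.json"], t0)

    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return out
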