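"""Pipeline orchestration: simulate -> filter -> kinship/sfs/diversity -> loh
-> embryos -> load, driven by a YAML run configuration.

Each stage writes its tables under ``<out>/<stage>/`` plus a manifest line
(stage, parameters, output checksums); a final ``report.tsv`` aggregates
clone counts, LOH fractions, sexual-embryo counts and load summaries.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, filtering, kinship, load, loh, simulate, vcfio

log = logging.getLogger("apomixis_scan")

STAGE_ORDER = ["simulate", "filter", "kinship", "sfs", "diversity", "loh", "embryos", "load"]

_DEFAULTS: dict = {
    "scenario": "clonal",
    "seed": 0,
    "tissue": "adult",
    "n_samples": 20,
    "sim": {},  # SimConfig overrides
    "filter": {},  # FilterConfig overrides
    "loh": {"window": 50_000, "cutoff": 0.001},
    "embryos": {
        "min_block_windows": 10,
        "min_novel_span": 2_000_000,
        "background_fraction": 0.8,
    },
    "load": {"outgroups": ["OUT1", "OUT2"]},
    "vcf": None,  # external input VCF (skips the simulate stage)
    "annotation": None,
    "genome_length": None,
}


@dataclass
class RunConfig:
    params: dict = field(default_factory=dict)
    out_dir: Path = Path("apomixis_run")

    def get(self, *keys, default=None):
        cur = self.params
        for k in keys:
            if not isinstance(cur, dict) or k not in cur:
                return default
            cur = cur[k]
        return cur


def validate_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Load and validate a YAML run config, reporting all problems at once."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as e:
        raise OSError(f"cannot read config: {e}") from e
    if not isinstance(raw, dict):
        return RunConfig(), ["config root must be a mapping"]
    params = {**_DEFAULTS}
    for k, v in raw.items():
        if k == "out":
            continue
        if k not in _DEFAULTS:
            log.warning("unknown config key %r ignored", k)
            continue
        if isinstance(_DEFAULTS.get(k), dict) and isinstance(v, dict):
            params[k] = {**_DEFAULTS[k], **v}
        else:
            params[k] = v
    if params["scenario"] not in ("sexual", "clonal", "hybrid", "embryos"):
        errors.append(f"scenario: unknown value {params['scenario']!r}")
    if not isinstance(params["seed"], int):
        errors.append("seed: must be an integer")
    c = params["loh"].get("cutoff")
    if c is not None and not 0 <= c <= 1:
        errors.append(f"loh.cutoff: {c} not in [0, 1]")
    for k, v in params["embryos"].items():
        if isinstance(v, (int, float)) and v < 0:
            errors.append(f"embryos.{k}: {v} must be >= 0")
    try:
        simulate.SimConfig(seed=params["seed"], **params["sim"])
    except (TypeError, simulate.ConfigurationError) as e:
        errors.append(f"sim: {e}")
    try:
        filtering.FilterConfig(**params["filter"])
    except (TypeError, ValueError) as e:
        errors.append(f"filter: {e}")
    cfg = RunConfig(params=params, out_dir=Path(raw.get("out", "apomixis_run")))
    return cfg, errors


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stateful pipeline execution with per-stage outputs and manifest."""

    def __init__(self, cfg: RunConfig, out_dir: Path | None = None, seed: int | None = None):
        self.cfg = cfg
        self.out = Path(out_dir or cfg.out_dir)
        self.seed = seed if seed is not None else cfg.get("seed", default=0)
        self.manifest: list[dict] = []
        self.state: dict = {}

    # -- helpers ---------------------------------------------------------- #

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.manifest.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _checksum(p) for p in outputs},
            }
        )

    def _require(self, key: str, stage: str, needed_by: str):
        if key not in self.state:
            raise RuntimeError(
                f"stage '{needed_by}' requires output of stage '{stage}' — "
                f"run it first or include it in --stages"
            )
        return self.state[key]

    def _sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(seed=self.seed, **self.cfg.get("sim", default={}))

    # -- stages ----------------------------------------------------------- #

    def stage_simulate(self) -> None:
        sc = self._sim_config()
        scenario = self.cfg.get("scenario", default="clonal")
        rng = np.random.default_rng(sc.seed + 10)
        if scenario == "sexual":
            m, truth = simulate.simulate_sexual_population(
                sc, self.cfg.get("n_samples", default=20)
            )
        elif scenario == "clonal":
            m, truth = simulate.simulate_clonal_complex(sc)
        elif scenario == "hybrid":
            m, truth = simulate.simulate_hybrid_apomict(
                sc, self.cfg.get("n_samples", default=20)
            )
        elif scenario == "embryos":
            m, truth, _ = simulate.simulate_embryo_scenario(sc)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        tissue = "embryo" if scenario == "embryos" else "adult"
        obs = simulate.apply_sequencing_model(m, sc, tissue=tissue, rng=rng)
        obs = simulate.add_outgroups(obs, truth, sc, rng=rng)
        ann = simulate.truth_annotation(m, truth)
        d = self._stage_dir("simulate")
        paths = simulate.write_simulation(obs, truth, ann, d / "sim")
        self.state.update(matrix=obs, truth=truth, annotation=ann, tissue=tissue)
        self._record("simulate", {"scenario": scenario, "seed": sc.seed},
                     list(paths.values()))

    def stage_filter(self) -> None:
        if "matrix" not in self.state and self.cfg.get("vcf"):
            self.state["matrix"] = vcfio.read_vcf(self.cfg.get("vcf"))
            self.state["tissue"] = self.cfg.get("tissue", default="adult")
        m = self._require("matrix", "simulate", "filter")
        fc = filtering.FilterConfig(**self.cfg.get("filter", default={}))
        tissue = self.state.get("tissue", "adult")
        if m.depth is not None:
            m = filtering.genotype_qc(m, fc, tissue=tissue)
        # lightly filtered set (biallelic + missing-rate only): the input
        # for kinship, h, SFS and diversity, which must not be thinned
        import dataclasses

        basic_cfg = dataclasses.replace(
            fc, drop_singletons=False, thin_window=0
        )
        basic, _ = filtering.site_filters(m, basic_cfg)
        # full six-step set for neutral-site analyses
        filtered, retention = filtering.site_filters(m, fc)
        d = self._stage_dir("filter")
        retention.to_csv(d / "retention.tsv", sep="\t", index=False)
        vcfio.write_vcf(filtered, d / "filtered.vcf")
        self.state["basic"] = basic
        self.state["filtered"] = filtered
        self._record("filter", {"tissue": tissue},
                     [d / "retention.tsv", d / "filtered.vcf"])

    def _analysis_samples(self, m):
        og = set(self.cfg.get("load", "outgroups", default=[]) or [])
        return [s for s in m.sample_ids if s not in og]

    def stage_kinship(self) -> None:
        m = self._require("basic", "filter", "kinship")
        sub = m.take_samples(self._analysis_samples(m))
        results = kinship.kinship_matrix(sub)
        graph = kinship.clone_components(results)
        d = self._stage_dir("kinship")
        kinship.kinship_table(results).to_csv(d / "kinship.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(s, i) for i, comp in enumerate(graph.components) for s in comp],
            columns=["sample", "clone_id"],
        ).to_csv(d / "clones.tsv", sep="\t", index=False)
        self.state["clone_graph"] = graph
        self._record("kinship", {}, [d / "kinship.tsv", d / "clones.tsv"])

    def stage_sfs(self) -> None:
        m = self._require("basic", "filter", "sfs")
        sub = m.take_samples(self._analysis_samples(m))
        sfs = diversity.folded_sfs(sub)
        d = self._stage_dir("sfs")
        sfs.to_frame().to_csv(d / "sfs.tsv", sep="\t", index=False)
        self._record("sfs", {"n_alleles": sfs.n_alleles}, [d / "sfs.tsv"])

    def stage_diversity(self) -> None:
        m = self._require("basic", "filter", "diversity")
        samples = self._analysis_samples(m)
        sub = m.take_samples(samples)
        div = diversity.windowed_diversity(sub, {"all": samples})
        het = diversity.individual_heterozygosity(
            sub, self.cfg.get("genome_length")
        )
        d = self._stage_dir("diversity")
        div.to_csv(d / "diversity.tsv", sep="\t", index=False)
        het.to_csv(d / "het.tsv", sep="\t", index=False)
        self.state["het"] = het
        self._record("diversity", {}, [d / "diversity.tsv", d / "het.tsv"])

    def stage_loh(self) -> None:
        m = self._require("matrix", "simulate", "loh")
        fc = filtering.FilterConfig(**self.cfg.get("filter", default={}))
        tissue = self.state.get("tissue", "adult")
        if m.depth is not None:
            m = filtering.genotype_qc(m, fc, tissue=tissue)
        samples = self._analysis_samples(m)
        window = self.cfg.get("loh", "window", default=50_000)
        cutoff = self.cfg.get("loh", "cutoff", default=0.001)
        tracks = loh.window_heterozygosity(m, window=window, tissue=tissue,
                                           samples=samples)
        profiles = [loh.call_loh(t, cutoff=cutoff) for t in tracks]
        d = self._stage_dir("loh")
        pd.concat(
            [p.windows.assign(sample=p.sample) for p in profiles], ignore_index=True
        ).to_csv(d / "het_windows.tsv", sep="\t", index=False)
        blocks = pd.concat(
            [p.blocks.assign(sample=p.sample, cutoff=cutoff) for p in profiles],
            ignore_index=True,
        )
        blocks.to_csv(d / "loh_blocks.bed", sep="\t", index=False)
        self.state["profiles"] = profiles
        self._record("loh", {"window": window, "cutoff": cutoff},
                     [d / "het_windows.tsv", d / "loh_blocks.bed"])

    def stage_embryos(self) -> None:
        profiles = self._require("profiles", "loh", "embryos")
        truth = self.state.get("truth")
        meta = truth.sample_meta if truth is not None else None
        by_mother: dict[str, list] = {}
        for p in profiles:
            mother = "M1"
            if meta is not None:
                row = meta.loc[meta["sample"] == p.sample]
                if len(row):
                    mother = str(row["mother"].iloc[0])
            by_mother.setdefault(mother, []).append(p)
        e = self.cfg.get("embryos", default={})
        classifications = loh.detect_sexual_embryos(
            by_mother,
            min_block_windows=e.get("min_block_windows", 10),
            min_novel_span=e.get("min_novel_span", 2_000_000),
            background_fraction=e.get("background_fraction", 0.8),
        )
        partition = loh.partition_loh(by_mother, classifications)
        d = self._stage_dir("embryos")
        pd.DataFrame(
            [(c.embryo, c.mother, c.label, c.novel_span) for c in classifications],
            columns=["embryo", "mother", "label", "novel_span"],
        ).to_csv(d / "embryo_calls.tsv", sep="\t", index=False)
        rows = []
        for mother, part in partition.items():
            rows += [(mother, w, "ancestral", ".") for w in sorted(part["ancestral"])]
            for emb, wins in part["novel"].items():
                rows += [(mother, w, "novel", emb) for w in sorted(wins)]
        pd.DataFrame(rows, columns=["mother", "window", "class", "embryo"]).to_csv(
            d / "loh_partition.tsv", sep="\t", index=False
        )
        self.state["classifications"] = classifications
        self.state["partition"] = partition
        self._record("embryos", e, [d / "embryo_calls.tsv", d / "loh_partition.tsv"])

    def stage_load(self) -> None:
        m = self._require("matrix", "simulate", "load")
        ann = self.state.get("annotation")
        if ann is None:
            ann_path = self.cfg.get("annotation")
            if ann_path is None:
                raise RuntimeError("stage 'load' requires an annotation (simulate "
                                   "stage or 'annotation' config path)")
            ann = load.SiteAnnotation.read_tsv(ann_path)
        og = self.cfg.get("load", "outgroups", default=["OUT1", "OUT2"])
        try:
            anc = load.polarize(m, og)
        except KeyError:
            anc = None  # fall back to annotation's ancestral column
        samples = self._analysis_samples(m)
        summary = load.load_counts(m, ann, ancestral=anc, samples=samples)
        ratios = load.load_ratios(summary)
        aligned = ann.aligned_to(m)
        z4 = load.zero_four_ratio(
            m.take_samples(samples), aligned["degeneracy"].to_numpy()
        )
        d = self._stage_dir("load")
        summary.to_csv(d / "load_summary.tsv", sep="\t", index=False)
        ratios.to_csv(d / "ratios.tsv", sep="\t", index=False)
        z4.to_csv(d / "zero_four.tsv", sep="\t", index=False)
        outputs = [d / "load_summary.tsv", d / "ratios.tsv", d / "zero_four.tsv"]
        if "profiles" in self.state:
            strat = load.region_stratified_load(
                m, ann, self.state["profiles"], ancestral=anc
            )
            strat.to_csv(d / "load_by_region.tsv", sep="\t", index=False)
            outputs.append(d / "load_by_region.tsv")
        self.state["load_summary"] = summary
        self._record("load", {"outgroups": og}, outputs)

    # -- report ----------------------------------------------------------- #

    def write_report(self) -> Path:
        rows = []
        if "clone_graph" in self.state:
            g = self.state["clone_graph"]
            rows.append(("n_clones", len([c for c in g.components if len(c) > 1])))
            rows.append(("n_samples_in_clones",
                         sum(len(c) for c in g.components if len(c) > 1)))
        if "profiles" in self.state:
            profiles = self.state["profiles"]
            calls = np.concatenate(
                [p.windows["call"].to_numpy() for p in profiles]
            )
            non_na = (calls != "NA").sum()
            rows.append(("loh_window_fraction",
                         (calls == "LOH").sum() / non_na if non_na else np.nan))
            rows.append(("mean_loh_blocks",
                         float(np.mean([p.n_blocks for p in profiles]))))
        if "classifications" in self.state:
            cl = self.state["classifications"]
            rows.append(("n_sexual_embryos",
                         sum(1 for c in cl if c.label == "sexual")))
            rows.append(("n_embryos", len(cl)))
        if "het" in self.state:
            rows.append(("mean_h", float(self.state["het"]["h"].mean())))
        if "load_summary" in self.state:
            s = self.state["load_summary"]
            for cls_name, sub in s.groupby("class"):
                rows.append((f"mean_total_derived_{cls_name}",
                             float(sub["total_derived"].mean())))
        report = self.out / "report.tsv"
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            report, sep="\t", index=False
        )
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return report


def run_pipeline(
    cfg: RunConfig,
    stages: list[str] | None = None,
    out_dir: Path | None = None,
    seed: int | None = None,
    dry_run: bool = False,
) -> Path:
    """Execute the requested stages in dependency order; returns the out dir."""
    stages = [s for s in STAGE_ORDER if s in (stages or STAGE_ORDER)]
    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    run = PipelineRun(cfg, out_dir=out_dir, seed=seed)
    if dry_run:
        log.info("dry run: would execute %s -> %s", stages, run.out)
        print(f"plan: {' -> '.join(stages)} (out: {run.out})")
        return run.out
    run.out.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        log.info("stage %s", stage)
        getattr(run, f"stage_{stage}")()
    run.write_report()
    return run.out


__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineRun", "STAGE_ORDER"]
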