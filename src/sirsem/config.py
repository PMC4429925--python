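"""Run configuration and end-to-end pipeline orchestration.

A single YAML file drives a run.  Recognised blocks::

    data: records.tsv          # phenotype records (fit stage)
    pedigree: pedigree.tsv     # sire-MGS pedigree (fit stage)
    model: M2                  # preset, or
    structure_file: edges.tsv  # custom "from <tab> to" pairs (not both)
    output: outdir
    chain: {n_iter: 120000, burn_in: 20000, thin: 10, seed: 1, ...}
    priors: {tau2: 10000, nu: 6, ...}
    simulate: {scale: 0.1, seed: 7, truth: M2}   # optional: generate data
    baseline: m0_chain_dir     # optional: fitted M0 chain for variance-loss
    report: {tables: true, traces: false}

Stages run in order simulate -> fit -> summarize; a stage is skipped when its
inputs are not configured.  Every output is listed in a manifest with
checksums, and the effective configuration is dumped beside the outputs so a
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigError
from .pedigree import read_pedigree, write_pedigree
from .sampler import ChainConfig, PosteriorChain, PriorSpec, run_chain
from .simulate import default_design, default_truth, read_records, simulate, write_records
from .structure import CausalStructure, make_structure, preset_structure
from .summaries import plot_traces, summarize_chain, write_summary_tables


@dataclass
class RunConfig:
    """Validated, normalized run configuration."""

    output: Path
    data: Path | None = None
    pedigree: Path | None = None
    model: str | None = None
    structure_file: Path | None = None
    chain: ChainConfig = field(default_factory=ChainConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    simulate: dict | None = None
    baseline: Path | None = None
    report: dict = field(default_factory=lambda: {"tables": True, "traces": False})

    def structure(self) -> CausalStructure:
        if self.model is not None:
            return preset_structure(self.model)
        if self.structure_file is not None:
            df = pd.read_csv(self.structure_file, sep=None, engine="python",
                             header=None, comment="#")
            return make_structure([(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)])
        raise ConfigError("no model preset or structure file configured")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    known = {"data", "pedigree", "model", "structure_file", "output", "chain",
             "priors", "simulate", "baseline", "report"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")

    if raw.get("model") is not None and raw.get("structure_file") is not None:
        raise ConfigError("model: set either a preset or structure_file, not both")
    if raw.get("model") is None and raw.get("structure_file") is None:
        raise ConfigError("model: a preset or structure_file is required")

    has_sim = "simulate" in raw and raw["simulate"] is not None
    if not has_sim:
        if raw.get("data") is None:
            raise ConfigError("data: a records file is required when not simulating")
        if raw.get("pedigree") is None:
            raise ConfigError("pedigree: a pedigree file is required when not simulating")
        for key in ("data", "pedigree"):
            if not Path(raw[key]).exists():
                raise ConfigError(f"{key}: file {raw[key]} does not exist")

    chain_kwargs = dict(raw.get("chain") or {})
    try:
        chain = ChainConfig(**chain_kwargs)
    except TypeError as exc:
        raise ConfigError(f"chain: {exc}") from exc
    try:
        priors = PriorSpec(**dict(raw.get("priors") or {}))
    except TypeError as exc:
        raise ConfigError(f"priors: {exc}") from exc

    sim = None
    if has_sim:
        sim = dict(raw["simulate"])
        bad = set(sim) - {"scale", "seed", "truth", "sires_per_herd"}
        if bad:
            raise ConfigError(f"simulate: unknown fields {sorted(bad)}")
        sim.setdefault("scale", 1.0)
        sim.setdefault("seed", chain.seed)
        sim.setdefault("truth", raw.get("model") or "M3")

    report = {"tables": True, "traces": False}
    report.update(dict(raw.get("report") or {}))

    return RunConfig(
        output=Path(raw.get("output", "sirsem_out")),
        data=Path(raw["data"]) if raw.get("data") else None,
        pedigree=Path(raw["pedigree"]) if raw.get("pedigree") else None,
        model=raw.get("model"),
        structure_file=Path(raw["structure_file"]) if raw.get("structure_file") else None,
        chain=chain,
        priors=priors,
        simulate=sim,
        baseline=Path(raw["baseline"]) if raw.get("baseline") else None,
        report=report,
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    out = config.output
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    manifest: dict = {"stages": [], "outputs": {}}

    structure = config.structure()

    data_path = config.data
    ped_path = config.pedigree
    if config.simulate is not None:
        sim_cfg = config.simulate
        truth_model = sim_cfg["truth"]
        if truth_model not in ("M0", "M1", "M2", "M3"):
            raise ConfigError(f"simulate.truth: no default truth for {truth_model!r}")
        design = default_design(
            seed=int(sim_cfg["seed"]), scale=float(sim_cfg["scale"]),
            sires_per_herd=int(sim_cfg.get("sires_per_herd", 15)),
        )
        truth = default_truth(truth_model)
        result = simulate(design, truth, seed=int(sim_cfg["seed"]))
        data_path = out / "records.tsv"
        ped_path = out / "pedigree.tsv"
        write_records(result.records, data_path)
        write_pedigree(design.pedigree, ped_path)
        produced += [data_path, ped_path]
        manifest["stages"].append("simulate")

    if data_path is None or ped_path is None:
        raise ConfigError("fit stage needs data and pedigree paths")
    records = read_records(data_path)
    pedigree = read_pedigree(ped_path)
    chain = run_chain(records, structure, pedigree,
                      priors=config.priors, config=config.chain)
    chain_dir = out / "chain"
    chain.save(chain_dir)
    produced += sorted(chain_dir.iterdir())
    manifest["stages"].append("fit")

    baseline = PosteriorChain.load(config.baseline) if config.baseline else None
    sds = {t: float(records[t].std(ddof=1)) for t in structure.traits.labels}
    summary = summarize_chain(chain, data_sds=sds, baseline=baseline)
    if config.report.get("tables", True):
        tab_dir = out / "tables"
        write_summary_tables(summary, tab_dir)
        produced += sorted(tab_dir.iterdir())
    if config.report.get("traces", False):
        fig = out / "traces.png"
        plot_traces(chain, fig)
        produced.append(fig)
    manifest["stages"].append("summarize")

    effective = {
        "model": config.model,
        "structure": [list(e) for e in structure.edges],
        "chain": {
            "n_iter": config.chain.n_iter, "burn_in": config.chain.burn_in,
            "thin": config.chain.thin, "seed": config.chain.seed,
        },
        "acceptance": chain.acceptance,
        "traits": list(structure.traits.labels),
        "calibration": {"n_records": int(len(records))},
        "package_defaults": {"nu": config.priors.nu, "tau2": config.priors.tau2},
    }
    (out / "effective_config.json").write_text(json.dumps(effective, indent=2))
    produced.append(out / "effective_config.json")

    for p in produced:
        manifest["outputs"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["RunConfig", "validate_config", "run_pipeline"]
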