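"""End-to-end orchestration of the profiling stages.

One YAML config drives the chain

    simulate/ingest -> normalize + specificity scoring -> benchmark
                    -> I-DIRT stability -> integration -> cluster/enrich/network

Each stage writes plain TSV outputs into the run directory and records a
SHA-256 digest per file in a run manifest (``manifest.json``). Re-running
with ``resume=True`` skips stages whose recorded outputs are intact and
refuses to run past an output whose digest no longer matches what the
manifest recorded (no silent overwrite of corrupted intermediates).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .benchmark import label_results, read_reference, recovery_report, roc_like_curve
from .countmatrix import (
    CountMatrix,
    clean_preys,
    identity_normalized,
    normalize_counts,
    read_count_matrix,
    zero_bait_self_counts,
)
from .errors import ConfigError, DataError, DependencyError
from .idirt import protein_stability, read_peptides, stability_to_frame
from .integration import ClassifyConfig
from .network import (
    cluster_matrix,
    enrichment_index,
    export_network,
    log2_counts,
    nsaf,
    write_sif,
)
from .saint import (
    SaintConfig,
    ThresholdPolicy,
    apply_thresholds,
    results_to_frame,
    score_bait,
)
from .simulate import SimConfig, generate_all

STAGES = [
    "simulate",
    "saint",
    "benchmark",
    "idirt",
    "integrate",
    "cluster",
    "enrich",
    "network",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    """Schema check with field-path error messages."""
    if "seed" not in cfg:
        raise ConfigError("seed: required")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: must be an integer")
    stages = cfg.get("stages", STAGES)
    if not isinstance(stages, list):
        raise ConfigError("stages: must be a list")
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"stages: unknown stage {s!r}")
    cfg["stages"] = stages
    sim = cfg.get("simulate", {})
    if not isinstance(sim, dict):
        raise ConfigError("simulate: must be a mapping")
    valid = {f.name for f in dataclass_fields(SimConfig)}
    for k in sim:
        if k not in valid:
            raise ConfigError(f"simulate.{k}: unknown field")
    for section in ("saint", "benchmark", "integrate", "enrich", "counts"):
        if section in cfg and not isinstance(cfg[section], dict):
            raise ConfigError(f"{section}: must be a mapping")
    return cfg


class Pipeline:
    """Stateful run of the configured stages into one output directory."""

    def __init__(self, cfg: dict[str, Any], outdir: str | Path, resume: bool = False):
        self.cfg = validate_config(dict(cfg))
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.seed = int(cfg["seed"])
        self.manifest: dict[str, Any] = {
            "version": __version__,
            "seed": self.seed,
            "config_hash": hashlib.sha256(
                json.dumps(self.cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "stages": [],
        }
        self._old_manifest = self._read_manifest() if resume else None
        # in-memory state shared between stages
        self._matrix: CountMatrix | None = None
        self._truth: pd.DataFrame | None = None

    # -- manifest helpers -------------------------------------------------

    def _read_manifest(self) -> dict[str, Any] | None:
        p = self.outdir / "manifest.json"
        if not p.exists():
            return None
        with open(p, "r", encoding="utf-8") as fh:
            return json.load(fh)

    def _recorded(self, stage: str) -> dict[str, str] | None:
        if not self._old_manifest:
            return None
        for s in self._old_manifest["stages"]:
            if s["name"] == stage:
                return s["outputs"]
        return None

    def _stage_intact(self, stage: str) -> bool:
        """True if all recorded outputs exist and match their digests."""
        outputs = self._recorded(stage)
        if outputs is None:
            return False
        for rel, digest in outputs.items():
            p = self.outdir / rel
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise DependencyError(
                    f"stage {stage!r}: output {rel} does not match its recorded "
                    "digest; refusing to resume past a corrupted intermediate"
                )
        return True

    def _record(self, stage: str, outputs: list[Path], started: float) -> None:
        self.manifest["stages"].append(
            {
                "name": stage,
                "outputs": {
                    str(p.relative_to(self.outdir)): _sha256(p) for p in outputs
                },
                "started": started,
                "finished": time.time(),
            }
        )

    def _require(self, rel: str) -> Path:
        p = self.outdir / rel
        if not p.exists():
            raise DependencyError(f"missing upstream file: {p}")
        return p

    # -- stage implementations -------------------------------------------

    def run(self) -> dict[str, Any]:
        for stage in self.cfg["stages"]:
            started = time.time()
            if self.resume and self._stage_intact(stage):
                self.manifest["stages"].append(
                    next(
                        s
                        for s in self._old_manifest["stages"]
                        if s["name"] == stage
                    )
                )
                continue
            outputs = getattr(self, f"_stage_{stage}")()
            self._record(stage, outputs, started)
        with open(self.outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2)
        return self.manifest

    def _stage_simulate(self) -> list[Path]:
        sim_cfg = SimConfig(seed=self.seed, **self.cfg.get("simulate", {}))
        paths = generate_all(sim_cfg, self.outdir)
        return sorted(paths.values())

    def _load_matrix(self) -> CountMatrix:
        if self._matrix is None:
            counts_cfg = self.cfg.get("counts", {})
            path = counts_cfg.get("file") or self._require("counts.tsv")
            dialect = counts_cfg.get("dialect", "long")
            m = read_count_matrix(path, dialect=dialect)
            m = clean_preys(m, counts_cfg.get("blocklist", []))
            m = zero_bait_self_counts(m)
            self._matrix = m
        return self._matrix

    def _threshold_policy(self) -> ThresholdPolicy:
        scfg = self.cfg.get("saint", {})
        return ThresholdPolicy(
            default=float(scfg.get("default_threshold", 0.75)),
            thresholds={
                k.upper(): float(v) for k, v in scfg.get("thresholds", {}).items()
            },
            strict=frozenset(scfg.get("strict", [])),
            manual_include=frozenset(
                (b, p) for b, p in scfg.get("manual_include", [])
            ),
        )

    def _stage_saint(self) -> list[Path]:
        m = self._load_matrix()
        scfg = self.cfg.get("saint", {})
        model = SaintConfig(
            pi_true=float(scfg.get("pi_true", 0.1)),
            pseudocount=float(scfg.get("pseudocount", 0.1)),
        )
        policy = self._threshold_policy()
        # totals-ratio normalization corrects differential acquisition depth;
        # disabled by default for runs acquired at a common depth
        do_normalize = bool(scfg.get("normalize", False))
        all_rows, filt_rows = [], []
        for bait in m.baits:
            norm = (
                normalize_counts(m, bait) if do_normalize else identity_normalized(m)
            )
            results = score_bait(norm, bait, model)
            filtered = apply_thresholds(results, policy)
            all_rows.append(results_to_frame(results))
            filt_rows.append(results_to_frame(filtered))
        out1 = self.outdir / "saint_results.tsv"
        out2 = self.outdir / "saint_filtered.tsv"
        pd.concat(all_rows, ignore_index=True).to_csv(out1, sep="\t", index=False)
        pd.concat(filt_rows, ignore_index=True).to_csv(out2, sep="\t", index=False)
        return [out1, out2]

    def _read_saint(self, filtered: bool = False) -> pd.DataFrame:
        name = "saint_filtered.tsv" if filtered else "saint_results.tsv"
        return pd.read_csv(self._require(name), sep="\t")

    def _stage_benchmark(self) -> list[Path]:
        from .saint import SaintResult

        bcfg = self.cfg.get("benchmark", {})
        ref_path = bcfg.get("reference") or self._require("reference.tsv")
        ref = read_reference(ref_path)
        df = self._read_saint()
        filt = self._read_saint(filtered=True)
        outputs = []
        recovery_rows = []
        for bait, sub in df.groupby("bait"):
            results = [
                SaintResult(bait=bait, prey=r.prey, iprobs=[], score=r.score)
                for r in sub.itertuples(index=False)
            ]
            label_results(results, ref)
            curve = roc_like_curve(results, ref)
            out = self.outdir / f"roc_{bait}.tsv"
            curve.to_frame().to_csv(out, sep="\t", index=False)
            outputs.append(out)
            passing = [
                SaintResult(
                    bait=bait, prey=r.prey, iprobs=[], score=r.score, passes=True
                )
                for r in filt[filt["bait"] == bait].itertuples(index=False)
            ]
            recovery_rows.append(
                {
                    "bait": bait,
                    "recovery": recovery_report(passing, ref, bait),
                    "auc": curve.auc(),
                }
            )
        out = self.outdir / "recovery.tsv"
        pd.DataFrame(recovery_rows).to_csv(out, sep="\t", index=False)
        outputs.append(out)
        return outputs

    def _baits(self) -> list[str]:
        return self._load_matrix().baits

    def _stage_idirt(self) -> list[Path]:
        outputs = []
        for bait in self._baits():
            path = self._require(f"peptides_{bait}.tsv")
            exp = read_peptides(path, bait)
            ratios = protein_stability(exp)
            out = self.outdir / f"stability_{bait}.tsv"
            stability_to_frame(ratios).to_csv(out, sep="\t", index=False)
            outputs.append(out)
        return outputs

    def _stage_integrate(self) -> list[Path]:
        from .integration import classify, profiles_to_frame, quadrant_summary
        from .integration import StabilityProfile

        icfg = self.cfg.get("integrate", {})
        policy = self._threshold_policy()
        df = self._read_saint()
        profiles: list[StabilityProfile] = []
        for bait in self._baits():
            thr, strict = policy.cutoff(bait)
            ccfg = ClassifyConfig(
                saint_pass=thr,
                strict=strict,
                stable_ratio=float(icfg.get("stable_ratio", 0.80)),
                contaminant_saint=float(icfg.get("contaminant_saint", 0.10)),
                contaminant_ratio=float(icfg.get("contaminant_ratio", 1.0)),
            )
            scores = {
                r.prey: r.score
                for r in df[df["bait"] == bait].itertuples(index=False)
            }
            stab = pd.read_csv(self._require(f"stability_{bait}.tsv"), sep="\t")
            ratios = dict(zip(stab["prey"], stab["idirt_ratio"]))
            for prey in sorted(set(scores) | set(ratios)):
                p = StabilityProfile(
                    bait=bait,
                    prey=prey,
                    saint_score=scores.get(prey),
                    idirt_ratio=ratios.get(prey),
                )
                p.category = classify(p.saint_score, p.idirt_ratio, ccfg)
                profiles.append(p)
        out1 = self.outdir / "profiles.tsv"
        profiles_to_frame(profiles).to_csv(out1, sep="\t", index=False)
        counts, _ = quadrant_summary(profiles)
        out2 = self.outdir / "quadrant_counts.tsv"
        pd.Series(counts, name="n").rename_axis("category").to_csv(out2, sep="\t")
        return [out1, out2]

    def _passing_preys(self) -> dict[str, set[str]]:
        filt = self._read_saint(filtered=True)
        return {
            bait: set(sub["prey"]) for bait, sub in filt.groupby("bait")
        }

    def _stage_cluster(self) -> list[Path]:
        m = self._load_matrix()
        passing = self._passing_preys()
        preys = sorted(set().union(*passing.values()) - set(m.baits)) if passing else []
        if len(preys) < 2:
            raise DataError("fewer than 2 SAINT-passing preys; nothing to cluster")
        run_ids = [r.run_id for r in m.runs if not r.is_control]
        mat = log2_counts(m.counts.loc[preys, run_ids])
        result = cluster_matrix(mat)
        out1 = self.outdir / "cluster_matrix.tsv"
        result.matrix.rename_axis("prey").to_csv(out1, sep="\t")
        out2 = self.outdir / "prey_dendrogram.nwk"
        out2.write_text(result.prey_newick() + "\n", encoding="utf-8")
        out3 = self.outdir / "run_dendrogram.nwk"
        out3.write_text(result.run_newick() + "\n", encoding="utf-8")
        return [out1, out2, out3]

    def _mean_bait_counts(self, bait: str, preys: list[str]) -> pd.Series:
        m = self._load_matrix()
        norm = normalize_counts(m, bait)
        cols = [r.run_id for r in norm.runs_for(bait)]
        return norm.counts.loc[preys, cols].mean(axis=1)

    def _stage_enrich(self) -> list[Path]:
        ecfg = self.cfg.get("enrich", {})
        pax_path = ecfg.get("pax") or self._require("pax.tsv")
        pax = pd.read_csv(pax_path, sep="\t", index_col=0).iloc[:, 0]
        passing = self._passing_preys()
        outputs = []
        for bait, preys in sorted(passing.items()):
            preys = sorted(preys)
            mean_counts = self._mean_bait_counts(bait, preys)
            values = nsaf(mean_counts, self._load_matrix().preys["length"])
            reference = ecfg.get("reference_prey") or values.idxmax()
            records = enrichment_index(values, pax, reference)
            out = self.outdir / f"enrichment_{bait}.tsv"
            pd.DataFrame(
                [
                    {
                        "prey": r.prey,
                        "nsaf": r.nsaf,
                        "pax_abundance": r.pax_abundance,
                        "enrichment_index": r.enrichment_index,
                    }
                    for r in records
                ]
            ).to_csv(out, sep="\t", index=False)
            outputs.append(out)
        return outputs

    def _stage_network(self) -> list[Path]:
        from .integration import StabilityProfile

        prof = pd.read_csv(self._require("profiles.tsv"), sep="\t")
        profiles = [
            StabilityProfile(
                bait=r.bait,
                prey=r.prey,
                saint_score=None if pd.isna(r.saint_score) else r.saint_score,
                idirt_ratio=None if pd.isna(r.idirt_ratio) else r.idirt_ratio,
                category=r.category,
            )
            for r in prof.itertuples(index=False)
        ]
        mean_counts: dict[tuple[str, str], float] = {}
        for bait in self._baits():
            preys = [p.prey for p in profiles if p.bait == bait]
            preys = [p for p in preys if p in self._load_matrix().counts.index]
            series = self._mean_bait_counts(bait, sorted(set(preys)))
            for prey, v in series.items():
                mean_counts[(bait, prey)] = float(v)
        ref_path = self.outdir / "reference.tsv"
        known = []
        if ref_path.exists():
            known = list(read_reference(ref_path).pairs)
        nodes, edges = export_network(profiles, mean_counts, known)
        out1 = self.outdir / "network_nodes.tsv"
        out2 = self.outdir / "network_edges.tsv"
        out3 = self.outdir / "network.sif"
        nodes.to_csv(out1, sep="\t", index=False)
        edges.to_csv(out2, sep="\t", index=False)
        write_sif(edges, out3)
        return [out1, out2, out3]


def run_pipeline(
    config: str | Path | dict[str, Any],
    outdir: str | Path | None = None,
    resume: bool = False,
) -> dict[str, Any]:
    """Run the configured stages; returns the run manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(dict(config))
    outdir = Path(outdir or cfg.get("outdir", "apms_run"))
    return Pipeline(cfg, outdir, resume=resume).run()
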