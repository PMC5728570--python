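"""End-to-end pipeline: simulate -> merge -> QC -> impute -> analyses.

A :class:`RunConfig` (typically loaded from YAML) toggles stages and carries
their parameter blocks.  :func:`run` executes the enabled stages in
dependency order, writes every artifact under ``out_dir`` and returns a
manifest listing each file with its stage, parameters, seed and SHA-256
checksum, so reruns with identical configuration are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, impute, io, ld, qc, sim, structure

log = logging.getLogger("panelpop")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "panelpop_run"
    seed: int = 0
    #: stage toggles, executed in this dependency order
    stages: dict = field(
        default_factory=lambda: {
            "sim": True, "merge": True, "qc": True, "impute": True,
            "ld": True, "structure": True, "fst": True,
        }
    )
    #: external inputs used when the sim stage is disabled
    input1: str | None = None
    input2: str | None = None
    sim_params: dict = field(default_factory=dict)
    qc_params: dict = field(default_factory=dict)
    ld_params: dict = field(default_factory=lambda: {"max_dist": None, "max_pairs": 200_000})
    structure_params: dict = field(default_factory=lambda: {"k": 3, "dialect": "ward.D"})
    fst_params: dict = field(
        default_factory=lambda: {
            "window_snps": 70, "n_regions": 4, "balanced_target": None,
            "theta_min": 0.6, "annotation": None,
        }
    )
    #: decimals used for percentage cells in written reports
    report_decimals: int = 2

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def _round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention of printed summary tables."""
    q = 10**decimals
    return float(np.sign(x) * np.floor(abs(x) * q + 0.5) / q)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; return the run manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []

    def emit(path: Path, stage: str, params: dict) -> None:
        artifacts.append(
            {
                "path": str(path.relative_to(out)),
                "stage": stage,
                "params": {k: (v if not isinstance(v, Path) else str(v))
                           for k, v in params.items()},
                "seed": config.seed,
                "sha256": _sha256(path),
            }
        )

    stages = config.stages
    truth = None
    gm1 = gm2 = None

    if stages.get("sim"):
        scfg = sim.SimConfig(**{**config.sim_params, "seed": config.seed})
        gm1, gm2, truth = sim.simulate_panel(scfg)
        p1, p2 = out / "platform1.vcf", out / "platform2.vcf"
        io.write_vcf(gm1, p1)
        io.write_vcf(gm2, p2)
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        pd.DataFrame(
            {"individual": truth.complete.individuals, "group": truth.group_labels}
        ).to_csv(tdir / "groups.tsv", sep="\t", index=False)
        pd.DataFrame(truth.pedigree, columns=["child", "parent1", "parent2"]).to_csv(
            tdir / "pedigree.tsv", sep="\t", index=False
        )
        params = dataclasses.asdict(scfg)
        for p in (p1, p2, tdir / "groups.tsv", tdir / "pedigree.tsv"):
            emit(p, "sim", params)
    elif config.input1:
        gm1 = io.read_genotypes(config.input1)
        gm2 = io.read_genotypes(config.input2) if config.input2 else None

    merged = None
    if stages.get("merge"):
        if gm1 is None:
            raise PipelineError("merge stage needs the sim stage or input paths")
        if gm2 is None:
            merged = gm1
            log.info("merge: single input, passing through")
        else:
            merged, report = io.merge(gm1, gm2)
            rp = out / "merge_report.tsv"
            df = report.to_frame()
            for col in ("Set 1", "Set 2", "Merged"):
                df[col] = [
                    _round_half_away(v, config.report_decimals)
                    if isinstance(v, float) else v
                    for v in df[col]
                ]
            df.to_csv(rp, sep="\t", index=False)
            mp = out / "merged.vcf"
            io.write_vcf(merged, mp)
            emit(rp, "merge", {})
            emit(mp, "merge", {})
    else:
        merged = gm1

    filtered = merged
    if stages.get("qc"):
        if merged is None:
            raise PipelineError("qc stage has no input matrix")
        fcfg = qc.FilterConfig(**config.qc_params)
        filtered, freport = qc.apply_filters(merged, fcfg)
        fp = out / "filtered.vcf"
        io.write_vcf(filtered, fp)
        rp = out / "qc_report.tsv"
        freport.summary().to_csv(rp, sep="\t", index=False)
        emit(fp, "qc", dataclasses.asdict(fcfg))
        emit(rp, "qc", dataclasses.asdict(fcfg))

    imputed = filtered
    if stages.get("impute"):
        if filtered is None:
            raise PipelineError("impute stage has no input matrix")
        model = impute.fit_markov(filtered)
        imputed = impute.impute_forward(filtered, model, seed=config.seed)
        ip = out / "imputed.vcf"
        io.write_vcf(imputed, ip)
        emit(ip, "impute", {"pseudocount": model.pseudocount})

    def require_complete(stage: str):
        if imputed is None:
            raise PipelineError(f"{stage} stage has no input matrix")
        if imputed.n_missing():
            raise PipelineError(
                f"{stage} stage requires fully imputed data but "
                f"{imputed.n_missing()} missing calls remain; enable the "
                "impute stage"
            )

    if stages.get("ld"):
        require_complete("ld")
        pairs = ld.pairwise_r2(
            imputed, seed=config.seed, **config.ld_params
        )
        curve = ld.decay_curve(pairs)
        pp = out / "ld_pairs.tsv"
        pairs.pairs.to_csv(pp, sep="\t", index=False)
        cp = out / "ld_curve.tsv"
        cdf = pd.DataFrame({"dist": curve.grid})
        for chrom, c in curve.curves.items():
            cdf[chrom] = c
        cdf.to_csv(cp, sep="\t", index=False)
        dp = out / "ld_decay.png"
        ld.plot_decay(curve, str(dp))
        for p in (pp, cp, dp):
            emit(p, "ld", {**config.ld_params, "d_star": curve.d_star["pooled"]})

    labels_for_fst = None
    if stages.get("structure"):
        require_complete("structure")
        pres = structure.pca(imputed)
        pca_path = out / "pca.tsv"
        pres.to_frame(min(10, pres.scores.shape[1])).to_csv(pca_path, sep="\t")
        eig_path = out / "eigenvalues.tsv"
        pd.DataFrame(
            {
                "component": np.arange(1, len(pres.eigenvalues) + 1),
                "eigenvalue": pres.eigenvalues,
                "pct_variance": pres.pct_variance,
            }
        ).to_csv(eig_path, sep="\t", index=False)
        dm = structure.nei_distance(imputed)
        tree = structure.ward_cluster(dm, dialect=config.structure_params.get("dialect", "ward.D"))
        nwk = out / "tree.nwk"
        nwk.write_text(structure.to_newick(tree) + "\n")
        k = int(config.structure_params.get("k", 3))
        groups = structure.cut_tree(tree, k)
        gp = out / "groups.tsv"
        groups.rename_axis("individual").to_frame().to_csv(gp, sep="\t")
        labels_for_fst = groups
        sp = {"k": k, "dialect": tree.dialect, "elbow": pres.elbow(),
              "inversions": tree.inversions()}
        for p in (pca_path, eig_path, nwk, gp):
            emit(p, "structure", sp)

    if stages.get("fst"):
        require_complete("fst")
        fp = config.fst_params
        if labels_for_fst is None:
            raise PipelineError(
                "fst stage requires group labels; enable the structure stage"
            )
        labels = labels_for_fst
        subset_note = {}
        if fp.get("balanced_target"):
            dm = structure.nei_distance(imputed)
            kept = diversity.select_balanced_unrelated(
                dm, labels, int(fp["balanced_target"])
            )
            roster = out / "fst_roster.tsv"
            pd.DataFrame(
                {
                    "individual": imputed.individuals,
                    "kept": [n in set(kept) for n in imputed.individuals],
                }
            ).to_csv(roster, sep="\t", index=False)
            emit(roster, "fst", {"balanced_target": fp["balanced_target"]})
            gm_fst = imputed.select_individuals(kept)
            labels = labels.loc[kept]
            subset_note = {"balanced_target": fp["balanced_target"]}
        else:
            gm_fst = imputed
        res = diversity.fst_weir_cockerham(gm_fst, labels)
        lp = out / "fst_per_locus.tsv"
        res.per_locus_frame().to_csv(lp, sep="\t", index=False)
        scan = diversity.fst_window_scan(res, int(fp.get("window_snps", 70)))
        wp = out / "fst_windows.tsv"
        scan.to_csv(wp, sep="\t", index=False)
        regions = diversity.top_regions(scan, int(fp.get("n_regions", 4)))
        bp = out / "fst_regions.bed"
        diversity.regions_to_bed(regions, str(bp))
        params = {**subset_note, "overall_theta": res.overall,
                  "window_snps": fp.get("window_snps", 70)}
        for p in (lp, wp, bp):
            emit(p, "fst", params)
        if fp.get("annotation"):
            ann = diversity.read_annotation(fp["annotation"])
            hits = diversity.candidate_genes(
                res, ann, theta_min=float(fp.get("theta_min", 0.6))
            )
            hp = out / "candidate_genes.tsv"
            pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
                hp, sep="\t", index=False
            )
            emit(hp, "fst", {"theta_min": fp.get("theta_min", 0.6)})

    manifest = {
        "seed": config.seed,
        "stages": {k: bool(v) for k, v in stages.items()},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
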