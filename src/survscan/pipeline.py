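"""End-to-end orchestration: normalize -> scan/permute -> Cox -> overlap.

A run is driven by a declarative YAML config (echoed verbatim into the
report) and writes one JSON report plus TSV artifacts.  Re-running with the
same config and seeds reproduces the outputs bit-identically apart from the
timestamp field.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cutpoint import CutpointSurvival, universal_threshold
from .expression import filter_low_expression, fpkm_log2, isoform_ratio, tmm_factors
from .io import (
    cohort_from_tables,
    read_counts,
    read_de_table,
    read_expression,
    read_survival,
    write_expression,
    write_factors,
    write_json,
)
from .overlap import make_signed_set, mc_overlap_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; see ``RunConfig.from_yaml``."""

    raw: dict
    out_dir: Path

    REQUIRED_STAGE_KEYS = {
        "normalize": ("counts", "lengths"),
        "survival": ("survival", "gene"),
        "universal": ("survival", "gene_a", "gene_b"),
        "overlap": ("table_a", "table_b"),
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        stages = raw.get("stages", {})
        if not stages:
            raise ValueError("config must request at least one stage")
        for name, stage in stages.items():
            if name not in cls.REQUIRED_STAGE_KEYS:
                raise ValueError(f"unknown stage {name!r}")
            for key in cls.REQUIRED_STAGE_KEYS[name]:
                if key not in stage:
                    raise ValueError(f"stage {name!r}: missing key {key!r}")
        for name, stage in stages.items():
            for key, val in stage.items():
                if key in ("counts", "lengths", "groups", "survival", "expression",
                           "table_a", "table_b") and val is not None:
                    if not Path(val).exists():
                        raise FileNotFoundError(f"stage {name!r}: {key} file {val}")
        return cls(raw=raw, out_dir=Path(raw["out_dir"]))


def _load_expression(stage: dict, report: dict, out_dir: Path):
    """Expression matrix for the survival stages: prebuilt file or prep output."""
    if "expression" in stage and stage["expression"]:
        return read_expression(stage["expression"])
    prep = out_dir / "expression.tsv"
    if prep.exists():
        return read_expression(prep)
    raise ValueError("no expression source: set stage key 'expression' or run normalize")


def _survival_cohort(stage: dict, em, gene: str):
    surv = read_survival(stage["survival"])
    if gene not in em.gene_ids:
        raise ValueError(f"gene id {gene!r} not present in the expression matrix")
    expr = pd.Series(em.row(gene), index=[str(s) for s in em.sample_ids])
    return cohort_from_tables(surv, expr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write the JSON report."""
    t0 = _time.time()
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.raw["stages"]
    seed = int(config.raw.get("seed", 0))
    report: dict = {
        "software": {"name": "survscan", "version": __version__},
        "config": config.raw,
        "stages": {},
    }

    if "normalize" in stages:
        st = stages["normalize"]
        cm = read_counts(st["counts"], st["lengths"], st.get("groups"))
        keep = filter_low_expression(
            cm,
            min_count=int(st.get("min_count", 10)),
            min_total=int(st.get("min_total", 15)),
        )
        cm_kept = cm.subset_genes(keep)
        nf = tmm_factors(
            cm_kept,
            trim_m=float(st.get("trim_m", 0.30)),
            trim_a=float(st.get("trim_a", 0.05)),
            reference=st.get("reference"),
        )
        em = fpkm_log2(cm_kept, nf)
        write_factors(nf, out_dir / "tmm_factors.tsv")
        write_expression(em, out_dir / "expression.tsv", nf)
        report["stages"]["normalize"] = {
            "n_genes_in": cm.n_genes,
            "n_genes_kept": cm_kept.n_genes,
            "reference_sample": nf.reference_sample,
            "factors": dict(zip(nf.sample_ids, nf.factors.tolist())),
            "scale": em.scale_tag,
        }
        if st.get("ratio_num") and st.get("ratio_den"):
            r = isoform_ratio(em, st["ratio_num"], st["ratio_den"])
            report["stages"]["normalize"]["isoform_ratio"] = {
                "num": r.iso_num,
                "den": r.iso_den,
                "cohort_ratio": r.cohort_ratio,
            }
        logger.info(
            "normalize: kept %d/%d genes, reference=%s",
            cm_kept.n_genes, cm.n_genes, nf.reference_sample,
        )

    if "survival" in stages:
        st = stages["survival"]
        em = _load_expression(st, report, out_dir)
        cohort = _survival_cohort(st, em, st["gene"])
        model = CutpointSurvival(cohort)
        res = model.fit(
            q_lo=float(st.get("q_lo", 0.10)),
            q_hi=float(st.get("q_hi", 0.90)),
            q_step=float(st.get("q_step", 0.01)),
            min_group=int(st.get("min_group", 2)),
            n_permutations=int(st.get("n_permutations", 10_000)),
            seed=int(st.get("seed", seed)),
            exceed_rule=st.get("exceed_rule", "strict"),
        )
        res.scan.to_table().to_csv(out_dir / "cutpoint_scan.tsv", sep="\t", index=False)
        report["stages"]["survival"] = {"gene": st["gene"], **res.to_dict()}
        logger.info(
            "survival: gene=%s cutpoint=%.4f perm_p=%.4g",
            st["gene"], res.best_threshold, res.p_value,
        )

    if "universal" in stages:
        st = stages["universal"]
        em = _load_expression(st, report, out_dir)
        cohort_a = _survival_cohort(st, em, st["gene_a"])
        cohort_b = _survival_cohort(st, em, st["gene_b"])
        ut = universal_threshold(
            cohort_a,
            cohort_b,
            min_group=int(st.get("min_group", 2)),
            n_permutations=int(st.get("n_permutations", 1000)),
            seed=int(st.get("seed", seed)),
            exceed_rule=st.get("exceed_rule", "strict"),
        )
        report["stages"]["universal"] = {
            "gene_a": st["gene_a"],
            "gene_b": st["gene_b"],
            **ut.to_dict(),
        }
        logger.info("universal: threshold=%.4f avg_p=%.4g", ut.threshold, ut.avg_p)

    if "overlap" in stages:
        st = stages["overlap"]
        det_a = read_de_table(st["table_a"])
        det_b = read_de_table(st["table_b"])
        universe = int(
            st.get("universe", len(set(det_a.gene_ids) | set(det_b.gene_ids)))
        )
        fc_min = float(st.get("fc_min", 1.5))
        fdr_max = float(st.get("fdr_max", 0.05))
        set_a = make_signed_set(det_a, fc_min, fdr_max, universe)
        set_b = make_signed_set(det_b, fc_min, fdr_max, universe)
        if st.get("flip_b", False):
            set_b = set_b.flipped()
        res = mc_overlap_test(
            set_a,
            set_b,
            n_iterations=int(st.get("n_iterations", 10_000)),
            statistic_mode=st.get("statistic_mode", "concordant"),
            seed=int(st.get("seed", seed)),
            exceed_rule=st.get("exceed_rule", "strict"),
        )
        report["stages"]["overlap"] = {
            "universe": universe,
            "n_a": len(set_a),
            "n_b": len(set_b),
            **res.to_dict(),
        }
        logger.info("overlap: %s", res.summary())

    report["wall_time_s"] = round(_time.time() - t0, 3)
    write_json(report, out_dir / "report.json")
    return report
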