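"""End-to-end orchestration: simulate/ingest -> connectivity -> feature
selection -> LOOCV classification -> FC-MMSE association.

Every stage writes plain-text artifacts (TSV/CSV/JSON) into the output
directory and records them, with SHA-256 checksums, in ``manifest.json``;
a run is reproducible byte-for-byte from its config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .classify import ClassifierSpec, loocv_curve
from .cohort import GROUP_NAMES, CohortSample, read_cohort, write_cohort
from .connectivity import DEFAULT_ALPHA, DEFAULT_CMAX, fc_matrix
from .discrepancy import (
    features_from_matrix,
    n_features,
    rank_features,
    select_top_fraction,
    significant_rois,
)
from .stats import fc_mmse_correlation
from .synthetic import Coupling, SyntheticSpec, generate_cohort

logger = logging.getLogger(__name__)

ALL_METHODS = ("pcc", "mic", "emic")
ALL_CONTRASTS = ((1, 2), (2, 3), (1, 3))


def contrast_name(contrast: tuple[int, int]) -> str:
    return f"{GROUP_NAMES[contrast[0]]}-{GROUP_NAMES[contrast[1]]}"


@dataclasses.dataclass
class RunConfig:
    out_dir: Path
    seed: int
    cohort_table: Path | None = None
    synthetic: SyntheticSpec | None = None
    methods: tuple[str, ...] = ALL_METHODS
    contrasts: tuple[tuple[int, int], ...] = ALL_CONTRASTS
    selection_fraction: float = 0.01
    classifier: ClassifierSpec = dataclasses.field(default_factory=ClassifierSpec)
    k_max: int | None = None
    alpha: float = DEFAULT_ALPHA
    cmax: int = DEFAULT_CMAX
    n_jobs: int = 1
    top_k_rois: int = 4

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.methods or not self.contrasts:
            raise ValueError("need at least one method and one contrast")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.cohort_table is None and self.synthetic is None:
            raise ValueError("provide either a cohort table or a synthetic recipe")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        syn = raw.pop("synthetic", None)
        if syn is not None:
            couplings = [
                Coupling(tuple(c["pair"]), c["transfer"], tuple(c["strength"]))
                for c in syn.pop("couplings", [])
            ]
            syn.setdefault("seed", raw.get("seed"))
            if syn["seed"] is None:
                raise ValueError("a seed is mandatory for synthetic cohorts")
            syn["group_sizes"] = tuple(syn.get("group_sizes", (21, 16, 13)))
            raw["synthetic"] = SyntheticSpec(couplings=couplings, **syn)
        if "classifier" in raw:
            raw["classifier"] = ClassifierSpec(**raw["classifier"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "cohort_table" in raw and raw["cohort_table"] is not None:
            raw["cohort_table"] = Path(raw["cohort_table"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        if d["cohort_table"] is not None:
            d["cohort_table"] = str(d["cohort_table"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def ingest_cohort(table_path: str | Path) -> CohortSample:
    """Validated cohort ingestion from a cohort table CSV."""
    return read_cohort(table_path)


def _subject_features(series, method, alpha, cmax):
    return features_from_matrix(fc_matrix(series, method, alpha, cmax))


def compute_features(
    cohort: CohortSample,
    method: str,
    alpha: float = DEFAULT_ALPHA,
    cmax: int = DEFAULT_CMAX,
    n_jobs: int = 1,
) -> np.ndarray:
    """Subjects x N feature matrix under one measure.  Per-subject work may
    be distributed; the result is independent of the worker count."""
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_subject_features)(s.series, method, alpha, cmax) for s in cohort.subjects
    )
    return np.vstack(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "config": config.echo(),
        "version": __version__,
        "seed": config.seed,
        "warnings": [],
    }

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    try:
        # -- stage: cohort -------------------------------------------------
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
        else:
            cohort = ingest_cohort(config.cohort_table)
        table_path = write_cohort(cohort, out / "cohort")
        for p in sorted((out / "cohort").iterdir()):
            record(p)
        r = cohort.n_regions
        n_feat = n_features(r)
        manifest["n_subjects"] = len(cohort.subjects)
        manifest["n_regions"] = r
        manifest["n_features"] = n_feat

        # -- stage: connectivity features ---------------------------------
        feats: dict[str, np.ndarray] = {}
        for method in ALL_METHODS:
            if method not in config.methods:
                logger.info("stage fc: skipping method %s", method)
                continue
            feats[method] = compute_features(
                cohort, method, config.alpha, config.cmax, config.n_jobs
            )
            fpath = out / f"features_{method}.csv"
            pd.DataFrame(
                feats[method],
                index=[s.series.subject_id for s in cohort.subjects],
            ).to_csv(fpath)
            record(fpath)

        # -- stages: selection, classification, association ----------------
        budget = config.k_max or int(np.ceil(config.selection_fraction * n_feat))
        manifest["selection_budget"] = budget
        codes = cohort.group_codes()
        mmse = cohort.mmse_scores()
        summaries = []
        for method, x in feats.items():
            for contrast in config.contrasts:
                cname = contrast_name(contrast)
                mask = np.isin(codes, contrast)
                table = rank_features(x[mask], codes[mask], contrast=contrast)
                select_top_fraction(table, config.selection_fraction)
                tpath = out / f"discrepancy_{method}_{cname}.csv"
                table.to_csv(tpath, cohort.region_labels)
                record(tpath)

                rois, edges = significant_rois(
                    table.selected, r, cohort.region_labels, config.top_k_rois
                )
                epath = out / f"edges_{method}_{cname}.tsv"
                edges.assign(abs_tau=np.abs(table.tau[table.selected])).to_csv(
                    epath, sep="\t", index=False
                )
                record(epath)

                curve = loocv_curve(
                    x[mask], codes[mask], config.classifier, k_max=budget
                )
                cpath = out / f"cv_{method}_{cname}.csv"
                curve.to_csv(cpath, method=method, scaling=config.classifier.scaling)
                record(cpath)
                record(cpath.with_suffix(".json"))
                summaries.append(
                    {
                        **curve.summary,
                        "method": method,
                        "contrast": cname,
                        "significant_rois": rois,
                    }
                )

                assoc = []
                for f in table.selected:
                    try:
                        rec = fc_mmse_correlation(x[:, f], mmse, feature=int(f))
                        assoc.append(
                            {
                                "feature": rec.feature,
                                "r": rec.r,
                                "p": rec.p,
                                "n": rec.n,
                                "significant": rec.significant,
                            }
                        )
                    except ValueError as err:
                        manifest["warnings"].append(f"association feature {f}: {err}")
                apath = out / f"association_{method}_{cname}.csv"
                pd.DataFrame(assoc).to_csv(apath, index=False)
                record(apath)
        manifest["results"] = summaries
    except Exception as exc:  # record partial progress, then re-raise
        manifest["failed"] = repr(exc)
        manifest["artifacts"] = artifacts
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["artifacts"] = artifacts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
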