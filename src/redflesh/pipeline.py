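"""End-to-end orchestration: scans → sections → descriptors → statistics → PLS.

One :class:`RunConfig` drives the whole chain.  Scan files are expected to be
named ``<genotype>.png`` or ``<genotype>_<year>.png``; the up-to-four sections
found in a scan are the fruit replicates of that genotype.  Every output table
starts with a comment header recording the package version, a hash of the
configuration and the seed, so a run can be audited and reproduced.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biochem import log_transform  # noqa: F401  (re-exported convenience)
from .colorimetry import aggregate_genotype, compute_descriptors, descriptors_to_frame
from .genstats import correlation_matrix, heritability, pca
from .pls import fit_pls1, prepare_design, validate
from .sections import extract_sections, load_scan, save_sections

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "visual_index", "read_config"]

DESCRIPTOR_COLS = [
    "R_mean", "G_mean", "B_mean", "R_sd", "G_sd", "B_sd",
    "L_mean", "a_mean", "b_mean", "L_sd", "a_sd", "b_sd",
]


@dataclass
class RunConfig:
    scans_dir: str
    out_dir: str
    profiles: str | None = None
    min_area: int | None = None
    hue_formula: str = "standard"
    responses: tuple[str, ...] = ("hue_deg", "a_mean", "b_mean")
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def digest(self) -> str:
        # out_dir excluded: the same analysis written elsewhere is the same run
        items = sorted((k, v) for k, v in self.__dict__.items() if k != "out_dir")
        return hashlib.sha256(repr(items).encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        if not Path(self.scans_dir).is_dir():
            raise FileNotFoundError(f"scans_dir does not exist: {self.scans_dir}")
        if self.profiles is not None and not Path(self.profiles).is_file():
            raise FileNotFoundError(f"profiles table does not exist: {self.profiles}")


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    args, extra = {}, {}
    for k, v in kv.items():
        if k not in known:
            extra[k] = v
        elif k == "min_area":
            args[k] = int(v)
        elif k == "seed":
            args[k] = int(v)
        elif k == "responses":
            args[k] = tuple(s.strip() for s in v.split(",") if s.strip())
        else:
            args[k] = v
    return RunConfig(**args, extra=extra)


def visual_index(scores) -> float:
    """Colour index of a genotype: mean of the per-fruit visual scores (0–5)."""
    scores = list(scores)
    if not 1 <= len(scores) <= 4:
        raise ValueError("expected 1–4 fruit scores")
    for s in scores:
        if not 0 <= s <= 5:
            raise ValueError(f"score {s} outside the 0–5 scale")
    if len(scores) < 4:
        log.warning("colour index from only %d fruit(s)", len(scores))
    return float(np.mean(scores))


def _parse_scan_name(stem: str) -> tuple[str, int]:
    if "_" in stem:
        head, _, tail = stem.rpartition("_")
        if tail.isdigit() and len(tail) == 4:
            return head, int(tail)
    return stem, 0


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, *, index=False) -> None:
    header = (
        f"# redflesh {__version__}; config={config.digest()}; seed={config.seed}\n"
    )
    path.write_text(header + df.to_csv(index=index))


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract → describe → aggregate → stats → PLS; return a report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.digest(), "seed": config.seed, "stages": {}}

    # --- extract ---------------------------------------------------------
    scan_paths = sorted(Path(config.scans_dir).glob("*.png"))
    if not scan_paths:
        raise FileNotFoundError(f"extract: no PNG scans found in {config.scans_dir}")
    manifest_rows, fruit_records = [], []
    crops_dir = out / "sections"
    for path in scan_paths:
        scan = load_scan(path)
        genotype, year = _parse_scan_name(scan.source_id)
        sections = extract_sections(scan, min_area=config.min_area)
        save_sections(scan, sections, crops_dir)
        for sec in sections:
            manifest_rows.append(
                {
                    "scan_id": scan.source_id,
                    "section_index": sec.label,
                    "row0": sec.bbox[0], "col0": sec.bbox[1],
                    "row1": sec.bbox[2], "col1": sec.bbox[3],
                    "area_px": sec.area_px,
                }
            )
            # --- describe (per fruit) --------------------------------
            fruit_records.append(
                compute_descriptors(
                    sec,
                    genotype_id=genotype,
                    fruit_id=f"{sec.label}",
                    year=year,
                    hue_formula=config.hue_formula,
                )
            )
    _write_table(pd.DataFrame(manifest_rows), out / "manifest.csv", config)
    report["stages"]["extract"] = {"scans": len(scan_paths), "sections": len(manifest_rows)}

    fruit_df = descriptors_to_frame(fruit_records)
    _write_table(fruit_df, out / "descriptors_fruit.csv", config)

    # --- aggregate -------------------------------------------------------
    agg_records = []
    for (gid, year), grp in sorted(
        pd.Series(range(len(fruit_records)))
        .groupby([fruit_df["genotype_id"], fruit_df["year"]])
        .groups.items()
    ):
        agg_records.append(
            aggregate_genotype(
                [fruit_records[i] for i in grp], hue_formula=config.hue_formula
            )
        )
    geno_df = descriptors_to_frame(agg_records)
    _write_table(geno_df, out / "descriptors_genotype.csv", config)
    report["stages"]["aggregate"] = {"genotype_years": len(geno_df)}

    # --- stats -----------------------------------------------------------
    if geno_df["year"].nunique() >= 2:
        h2_rows = []
        for trait in DESCRIPTOR_COLS + ["hue_deg", "chroma"]:
            model = heritability(
                geno_df.rename(columns={trait: "value"}), value_col="value", trait=trait
            )
            h2_rows.append({"trait": trait, "h2": model.h2,
                            "sigma2_B": model.sigma2_B, "sigma2_eps": model.sigma2_eps})
        _write_table(pd.DataFrame(h2_rows), out / "heritability.csv", config)
        report["stages"]["heritability"] = {"traits": len(h2_rows)}

    pooled = geno_df.groupby("genotype_id", as_index=True)[
        DESCRIPTOR_COLS + ["hue_deg", "chroma"]
    ].mean()
    active = pooled[DESCRIPTOR_COLS]
    prof_df = None
    sup = None
    if config.profiles:
        prof_df = pd.read_csv(config.profiles, comment="#")
        sup_cols = [c for c in prof_df.columns if c != "genotype_id"]
        sup = prof_df.set_index("genotype_id").reindex(pooled.index)[sup_cols]
    res = pca(active, supplementary=sup)
    eigen = pd.DataFrame(
        {"eigenvalue": res.eigenvalues, "pct_variance": res.pct_variance},
        index=[f"PC{i+1}" for i in range(len(res.eigenvalues))],
    )
    _write_table(eigen, out / "pca_eigen.csv", config, index=True)
    _write_table(res.scores, out / "pca_scores.csv", config, index=True)
    load_tab = res.loadings.copy()
    if res.sup_correlations is not None:
        load_tab = pd.concat(
            [load_tab.assign(role="active"), res.sup_correlations.assign(role="supplementary")]
        )
    _write_table(load_tab, out / "pca_loadings.csv", config, index=True)
    report["stages"]["pca"] = {"pc1_pct": float(res.pct_variance[0])}

    if prof_df is not None:
        joined = pooled.join(prof_df.set_index("genotype_id"), how="inner")
        corr = correlation_matrix(joined)
        _write_table(corr.r, out / "corr_r.csv", config, index=True)
        _write_table(corr.p, out / "corr_p.csv", config, index=True)
        report["stages"]["correlation"] = {"variables": corr.r.shape[0]}

        # --- pls ---------------------------------------------------------
        geno_desc = pooled.reset_index()
        for response in config.responses:
            X, y = prepare_design(prof_df, geno_desc, response=response)
            model = fit_pls1(X, y)
            vip_tab = pd.DataFrame(
                {
                    "predictor": model.predictor_names,
                    "coefficient": model.coefficients,
                    "vip": model.vip,
                    "important": model.important,
                }
            )
            _write_table(vip_tab, out / f"pls_{response}_vip.csv", config)
            rep = validate(X, y, seed=config.seed)
            summary = pd.DataFrame(
                [
                    {
                        "response": response,
                        "n_components": model.n_components,
                        "r2y_cum": model.r2y_cum,
                        "rmse_test": rep.rmse_test,
                        "n": len(y),
                        "split_seed": rep.seed,
                    }
                ]
            )
            _write_table(summary, out / f"pls_{response}_summary.csv", config)
            preds = pd.DataFrame(
                {"genotype_id": X.index, "observed": y, "predicted": model.predict(X)}
            )
            _write_table(preds, out / f"pls_{response}_predictions.csv", config)
            report["stages"][f"pls_{response}"] = {
                "n_components": model.n_components,
                "r2y_cum": model.r2y_cum,
                "rmse_test": rep.rmse_test,
            }
    return report
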