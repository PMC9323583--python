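"""End-to-end orchestration: simulate or load a cohort, estimate per-image
fractal dimensions, assemble the scan comparisons, and compute the full
reliability report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as imio
from .boxcount import estimate_fd
from .cohort import StudyDesign, assemble_comparisons
from .errors import ConfigurationError, InputError
from .preprocess import DEFAULT_THRESHOLD
from .reliability import (
    bland_altman,
    cicchetti_label,
    cv,
    format_proportion,
    icc,
    normality_check,
    paired_t,
    summarize,
)
from .synthetic import (
    ScanPerturbation,
    VesselTreeParams,
    default_inter_perturbation,
    default_intra_perturbation,
    generate_cohort,
)

log = logging.getLogger("fdretina")

STUDY_YEAR = 2018  # reference year for synthetic ages


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_dir`` (pre-rendered images + metadata.csv) or
    ``simulate`` (number of synthetic participants) must be set.
    """

    output_dir: str = "fdretina_out"
    input_dir: Optional[str] = None
    simulate: Optional[int] = None
    threshold: float = DEFAULT_THRESHOLD
    icc_model: str = "ICC_2_1"
    seed: int = 0
    vessel: VesselTreeParams = field(default_factory=VesselTreeParams)
    intra: ScanPerturbation = field(default_factory=default_intra_perturbation)
    inter: ScanPerturbation = field(default_factory=default_inter_perturbation)
    save_images: bool = False

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of input_dir / simulate must be given")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError("threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "vessel" in kwargs:
            kwargs["vessel"] = VesselTreeParams(**kwargs["vessel"])
        for key in ("intra", "inter"):
            if key in kwargs:
                d = dict(kwargs[key])
                if "shift_px" in d:
                    d["shift_px"] = tuple(d["shift_px"])
                kwargs[key] = ScanPerturbation(**d)
        return cls(**kwargs)


def _load_cohort(input_dir: str):
    root = Path(input_dir)
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise InputError(f"metadata.csv not found in {root}")
    metadata = pd.read_csv(meta_path)
    images = {}
    for row in metadata.itertuples():
        key = (row.participant_id, row.plexus, int(row.scan_index))
        images[key] = imio.read_image(root / row.image_path)
    return images, metadata


def estimate_cohort_fd(images: dict, metadata: pd.DataFrame,
                       threshold: float) -> pd.DataFrame:
    """Per-image FD table over a cohort's images."""
    rows = []
    for row in metadata.itertuples():
        key = (row.participant_id, row.plexus, int(row.scan_index))
        result = estimate_fd(images[key], threshold)
        rows.append({
            "participant_id": row.participant_id,
            "observer_id": int(row.observer_id),
            "scan_index": int(row.scan_index),
            "plexus": row.plexus,
            "fd": result.fd,
            "r_squared": result.r_squared,
            "n_scales": result.n_scales,
            "threshold_used": threshold,
        })
    return pd.DataFrame(rows)


def reliability_report(fd_table: pd.DataFrame,
                       icc_model: str = "ICC_2_1") -> pd.DataFrame:
    """One row per plexus x comparison with the full agreement statistics."""
    tables, _ = assemble_comparisons(fd_table, StudyDesign())
    rows = []
    for (plexus, comparison), pair in sorted(tables.items()):
        if pair.shape[0] < 3:
            continue
        a, b = pair.columns.tolist()
        x = pair[a].to_numpy()
        y = pair[b].to_numpy()
        res = icc(pair.to_numpy(), model=icc_model)
        ba = bland_altman(x, y)
        try:
            t_stat, p_val = paired_t(x, y)
        except InputError:
            t_stat, p_val = 0.0, 1.0
        cv_pair = cv([[v, w] for v, w in zip(x, y)]).cv_percent
        rows.append({
            "plexus": plexus,
            "comparison": comparison,
            "scan_a": a,
            "scan_b": b,
            "n": pair.shape[0],
            "icc": res.estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "model": res.model,
            "label": cicchetti_label(res.estimate),
            "cv_percent": cv_pair,
            "bias": ba.bias,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "t": t_stat,
            "p": p_val,
        })
    return pd.DataFrame(rows)


def descriptive_summary(fd_table: pd.DataFrame,
                        metadata: pd.DataFrame) -> dict:
    """Cohort-level descriptives: demographics and per-observer FD."""
    per_participant = metadata.drop_duplicates("participant_id")
    n = len(per_participant)
    right = int((per_participant["eye"] == "right").sum())
    right_pct, right_fmt = format_proportion(right, n)
    summary: dict = {
        "n_participants": n,
        "study_eye_right": {"count": right, "percent": right_pct,
                            "formatted": right_fmt},
    }
    if "birth_year" in per_participant.columns:
        ages = STUDY_YEAR - per_participant["birth_year"].to_numpy()
        summary["age_years"] = summarize(ages, decimals=1)
    fd_blocks = {}
    for (plexus, observer), grp in fd_table.groupby(["plexus", "observer_id"]):
        values = grp["fd"].to_numpy()
        block = summarize(values, decimals=3)
        if 3 <= values.size <= 5000 and np.ptp(values) > 0:
            w, p = normality_check(values)
            block["shapiro_w"], block["shapiro_p"] = w, p
        fd_blocks[f"{plexus}_observer{observer}"] = block
    summary["fd"] = fd_blocks
    return summary


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory tables; writes per-image FD CSV,
    reliability CSV/JSON, Bland-Altman pair CSVs and the descriptive
    summary JSON under ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        log.info("simulating cohort: n=%d seed=%d", config.simulate,
                 config.seed)
        images, metadata = generate_cohort(
            config.simulate, config.vessel, config.intra, config.inter,
            seed=config.seed)
        if config.save_images:
            for (pid, plexus, scan), img in images.items():
                imio.write_image(out / "images" /
                                 f"{pid}_{plexus}_scan{scan}.png", img)
    else:
        images, metadata = _load_cohort(config.input_dir)

    log.info("estimating FD for %d images", len(images))
    fd_table = estimate_cohort_fd(images, metadata, config.threshold)
    fd_table.to_csv(out / "fd_per_image.csv", index=False)

    report = reliability_report(fd_table, config.icc_model)
    report.to_csv(out / "reliability.csv", index=False)
    report.to_json(out / "reliability.json", orient="records", indent=2)

    tables, _ = assemble_comparisons(fd_table, StudyDesign())
    for (plexus, comparison), pair in sorted(tables.items()):
        if pair.shape[0] < 3:
            continue
        a, b = pair.columns.tolist()
        ba = bland_altman(pair[a].to_numpy(), pair[b].to_numpy())
        pd.DataFrame(ba.pairs, columns=["mean", "difference"]).to_csv(
            out / f"bland_altman_{plexus}_{comparison}.csv", index=False)

    summary = descriptive_summary(fd_table, metadata)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    metadata.to_csv(out / "metadata.csv", index=False)

    provenance = {"config": {
        k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
        for k, v in asdict(config).items()}}
    with open(out / "run_config.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    return {"fd_table": fd_table, "reliability": report,
            "summary": summary, "metadata": metadata}
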