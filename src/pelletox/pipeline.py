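"""End-to-end orchestration: images -> weathering -> endpoints -> regression.

Mirrors the study workflow: characterize pellet photographs (%YI),
summarize visual weathering scores, compute SET toxicity endpoints per
leachate, and regress undiluted-leachate toxicity on the weathering
metrics.  Every run writes a JSON manifest recording the configuration,
seeds, package version and input checksums; identical configurations
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import YI_STANDARD_NAME, get_illuminant_observer
from .dose_response import (
    CONTROL,
    derive_endpoints,
    endpoints_table,
    normalize_to_control,
    read_bioassays,
)
from .pellet_image import analyze_images
from .regression import regression_table
from .synthetic import (
    BioassaySimSpec,
    PelletImageSpec,
    make_pellet_image,
    make_score_table,
    simulate_bioassay,
)
from .weathering import read_observations, summarize_sample, summarize_table

__all__ = ["RunConfig", "run_end_to_end", "build_demo", "bioassays_to_frames"]

_CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of an end-to-end run; round-trips through YAML."""

    illuminant_observer: str = "D65/2"
    k_colors: int = 10
    seeds: dict = field(
        default_factory=lambda: {"clustering": 0, "dunnett": 0}
    )
    alpha: float = 0.05
    gating: str = "standard"  # or "literal"
    aggregation: str = "weighted_mean"
    background_policy: str = "alpha"
    reference_sample: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def undiluted_growth_pct(ds) -> float:
    """Mean larval growth in the undiluted leachate as % of control."""
    norm = normalize_to_control(ds)
    treat = norm[norm["treatment"] != CONTROL]
    dmax = treat["treatment"].astype(float).max()
    at_max = treat[treat["treatment"].astype(float) == dmax]
    return float(100.0 * at_max["r"].mean())


def run_end_to_end(
    config: RunConfig,
    image_manifest: str | os.PathLike,
    scores_csv: str | os.PathLike,
    bioassay_csv: str | os.PathLike,
    metadata_csv: str | os.PathLike,
    output_dir: str | os.PathLike,
) -> dict:
    """Run the full chain and write the result bundle to ``output_dir``.

    Outputs: images.csv, clusters.csv, weathering.csv (plus
    weathering_ratios.csv when a reference sample is configured),
    endpoints.csv, regression.csv and manifest.json.  Returns the
    manifest dictionary.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    io = get_illuminant_observer(config.illuminant_observer)

    # Stage 1: image yellowness.
    manifest_df = pd.read_csv(image_manifest)
    img_df, cluster_df = analyze_images(
        manifest_df,
        k=config.k_colors,
        seed=int(config.seeds.get("clustering", 0)),
        io=io,
        background_policy=config.background_policy,
        aggregation=config.aggregation,
    )
    img_df["yi_standard"] = YI_STANDARD_NAME
    img_df["illuminant_observer"] = io.name
    _write_csv(img_df, outdir / "images.csv")
    _write_csv(cluster_df, outdir / "clusters.csv")

    # Stage 2: weathering summaries.
    obs = read_observations(scores_csv)
    weath_df = summarize_table(obs)
    _write_csv(weath_df, outdir / "weathering.csv")
    if config.reference_sample is not None:
        from .weathering import weathering_increase

        by_sample = {}
        for o in obs:
            by_sample.setdefault(o.sample_id, []).append(o)
        ref = summarize_sample(by_sample[config.reference_sample])
        rows = []
        for sid in sorted(by_sample):
            s = summarize_sample(by_sample[sid])
            rows.append(
                dict(
                    reference=config.reference_sample,
                    sample_id=sid,
                    ratio_pct=weathering_increase(ref, s, "ratio"),
                    percent_change=weathering_increase(ref, s, "percent_change"),
                )
            )
        _write_csv(pd.DataFrame(rows), outdir / "weathering_ratios.csv")

    # Stage 3: toxicity endpoints.
    datasets = read_bioassays(bioassay_csv, metadata_csv)
    results = [
        derive_endpoints(
            ds,
            alpha=config.alpha,
            gating=config.gating,
            seed=int(config.seeds.get("dunnett", 0)),
        )
        for ds in datasets
    ]
    endp_df = endpoints_table(results)
    _write_csv(endp_df, outdir / "endpoints.csv")

    # Stage 4: regression of toxicity on weathering metrics.
    growth_rows = [
        dict(sample_id=ds.sample_id, growth_pct_control=undiluted_growth_pct(ds))
        for ds, r in zip(datasets, results)
        if r.acceptability.passed
    ]
    yi_per_sample = (
        img_df.groupby("sample_id", as_index=False)["sample_yi"].mean()
    )
    merged = (
        weath_df[["sample_id", "weathering_pct", "pct_ge2"]]
        .merge(yi_per_sample, on="sample_id", how="inner")
        .merge(pd.DataFrame(growth_rows), on="sample_id", how="inner")
    )
    _write_csv(merged, outdir / "regression_input.csv")
    if len(merged) >= 3:
        reg_df = regression_table(merged)
    else:
        reg_df = pd.DataFrame(
            columns=["predictor", "n", "slope", "intercept", "r_squared",
                     "p_slope", "band"]
        )
    _write_csv(reg_df, outdir / "regression.csv")

    manifest = {
        "package": "pelletox",
        "version": __version__,
        "yi_standard": YI_STANDARD_NAME,
        "config": dataclasses.asdict(config),
        "inputs": {
            str(p): _sha256(p)
            for p in (image_manifest, scores_csv, bioassay_csv, metadata_csv)
        },
        "outputs": sorted(
            f.name for f in outdir.iterdir() if f.suffix == ".csv"
        ),
        "rejected_assays": [
            {"sample_id": r.sample_id, "reasons": r.acceptability.reasons}
            for r in results
            if not r.acceptability.passed
        ],
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def bioassays_to_frames(datasets) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten BioassayDatasets to the long CSV schema plus metadata."""
    rows, meta = [], []
    for ds in datasets:
        meta.append(
            dict(
                sample_id=ds.sample_id,
                egg_mean_um=ds.egg_mean_um,
                fertilization_pct=ds.fertilization_pct,
            )
        )
        for v in ds.vials:
            # repr gives the shortest digit string that round-trips exactly
            treatment = CONTROL if v.is_control else repr(float(v.treatment))
            for i, ln in enumerate(v.lengths_um, start=1):
                rows.append(
                    dict(
                        sample_id=ds.sample_id,
                        treatment=treatment,
                        vial_id=v.vial_id,
                        larva_id=f"l{i:02d}",
                        length_um=float(ln),
                    )
                )
    return pd.DataFrame(rows), pd.DataFrame(meta)


# Demo stations: a near-source, lightly weathered stock; an intermediate
# beach; and a distant, heavily weathered beach.  Score counts give the
# canonical 86% / 49% / 46%+46% patterns; simulated EC50s grade from
# effectively non-toxic to clearly toxic.
_DEMO_STATIONS = [
    dict(sample_id="TR", tint=0.02, counts=(30, 5, 0), ec50=30.0),
    dict(sample_id="PI", tint=0.35, counts=(10, 17, 8), ec50=0.9),
    dict(sample_id="CA", tint=0.60, counts=(3, 16, 16), ec50=0.33),
]


def build_demo(output_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write a complete synthetic three-station demo input bundle.

    Two pellet images per station (increasing yellow tint), a 35-pellet
    score table per station, and one simulated bioassay per station with
    toxicity increasing away from the source.  A fourth assay ("QC") with
    sub-threshold fertilization exercises the acceptability rejection
    path.  Returns a dict of the written file paths.
    """
    outdir = Path(output_dir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    manifest_rows = []
    for st in _DEMO_STATIONS:
        for i in range(2):
            img_seed = int(rng.integers(0, 2**31 - 1))
            spec = PelletImageSpec(
                width=72,
                height=72,
                base_gray=215,
                yellow_tint=st["tint"] + 0.05 * i,
                crack_fraction=0.05 * i,
                seed=img_seed,
            )
            path = outdir / "images" / f"{st['sample_id']}_{i + 1}.png"
            make_pellet_image(spec, path)
            manifest_rows.append(dict(sample_id=st["sample_id"], path=str(path)))
    manifest_path = outdir / "images_manifest.csv"
    _write_csv(pd.DataFrame(manifest_rows), manifest_path)

    obs = []
    for st in _DEMO_STATIONS:
        obs.extend(
            make_score_table(
                st["sample_id"], st["counts"], seed=int(rng.integers(0, 2**31 - 1))
            )
        )
    scores_path = outdir / "scores.csv"
    _write_csv(
        pd.DataFrame(
            dict(
                sample_id=o.sample_id,
                pellet_id=o.pellet_id,
                yellowing=int(o.yellowing),
                cracking=int(o.cracking),
            )
            for o in obs
        ),
        scores_path,
    )

    datasets = []
    for st in _DEMO_STATIONS:
        spec = BioassaySimSpec(
            ec50=st["ec50"], seed=int(rng.integers(0, 2**31 - 1))
        )
        datasets.append(simulate_bioassay(spec, sample_id=st["sample_id"]))
    # Acceptability-failing assay: fertilization below the 95% threshold.
    bad = BioassaySimSpec(
        ec50=0.5, fertilization_pct=93.0, seed=int(rng.integers(0, 2**31 - 1))
    )
    datasets.append(simulate_bioassay(bad, sample_id="QC"))
    data_df, meta_df = bioassays_to_frames(datasets)
    bioassay_path = outdir / "bioassay.csv"
    metadata_path = outdir / "bioassay_meta.csv"
    _write_csv(data_df, bioassay_path)
    _write_csv(meta_df, metadata_path)

    return dict(
        image_manifest=str(manifest_path),
        scores_csv=str(scores_path),
        bioassay_csv=str(bioassay_path),
        metadata_csv=str(metadata_path),
    )
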