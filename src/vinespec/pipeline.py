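"""Config-driven end-to-end runs: simulate → allocate → filter → preprocess
→ screen → train → map.

A :class:`RunConfig` captures every stage parameter; :func:`run_all`
executes the stages in order, writes the artifacts (streams, chemistry,
dataset, model statistics, model documents, rasters) into an output
directory and returns a :class:`RunManifest` of per-stage counts, artifact
hashes and timings.  Identical configs yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .spectra_io import (
    ANALYTES,
    BlockChemistry,
    BlockRecord,
    SpectralStream,
    config_hash,
    write_blocks,
    write_chemistry,
    write_stream,
)
from .synthetic import (
    AnalyteFieldParams,
    SimConfig,
    VineyardLayout,
    default_endmembers,
    generate_chemistry,
    generate_layout,
    generate_stream,
    make_signature,
)
from .filtering import (
    DEFAULT_MIN_COUNT,
    DEFAULT_THRESHOLD,
    average_block,
    filter_stream,
)
from .preprocessing import TreatmentChain, apply_chain
from .chemometrics import (
    CalibrationDataset,
    ModelStats,
    detect_outliers,
    train_analyte,
)
from .mapping import render_series, write_esri_ascii

DEFAULT_TREATMENTS = {
    "tss": "D1W15",
    "anthocyanins": "D1W15",
    "polyphenols": "SNV + DT D1W15",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class FilterConfig:
    threshold: float = DEFAULT_THRESHOLD
    min_count: int = DEFAULT_MIN_COUNT
    centered: bool = False


@dataclass
class ModelConfig:
    calibration_fraction: float = 0.8
    n_folds: int = 10
    max_lv: int = 15
    r2_mode: str = "explained"
    outlier_alpha: float = 0.99


@dataclass
class MapConfig:
    cell_size: float = 1.0
    n_levels: int = 8
    mask_distance: float = 4.40  # 2 × row spacing


@dataclass
class RunConfig:
    """Everything a full run needs; one YAML document round-trips it."""

    seed: int = 0
    n_dates: int = 4
    layout: VineyardLayout = field(default_factory=VineyardLayout)
    sim: SimConfig = field(default_factory=SimConfig)
    analytes: AnalyteFieldParams = field(default_factory=AnalyteFieldParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    treatments: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS))
    model: ModelConfig = field(default_factory=ModelConfig)
    map: MapConfig = field(default_factory=MapConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        def build(tp, data):
            if data is None:
                return tp()
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in data:
                    continue
                v = data[f.name]
                if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
                    v = build(f.type, v)
                kwargs[f.name] = v
            return tp(**kwargs)

        cfg = cls()
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            current = getattr(cfg, f.name)
            if dataclasses.is_dataclass(current) and isinstance(v, dict):
                nested = {}
                for sub in dataclasses.fields(type(current)):
                    if sub.name in v:
                        sv = v[sub.name]
                        sub_current = getattr(current, sub.name)
                        if dataclasses.is_dataclass(sub_current) \
                                and isinstance(sv, dict):
                            sv = build(type(sub_current), sv)
                        elif isinstance(sub_current, tuple) \
                                and isinstance(sv, list):
                            sv = tuple(sv)
                        nested[sub.name] = sv
                v = dataclasses.replace(current, **nested)
            setattr(cfg, f.name, v)
        return cfg


@dataclass
class RunManifest:
    """Per-stage record of what a run consumed and produced."""

    config_hash: str
    software_version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, **info: Any) -> None:
        self.stages[stage] = info

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class SimulatedCampaign:
    """The synthetic world of one run: geometry, truth and raw streams."""

    blocks: list[BlockRecord]
    chemistry: list[BlockChemistry]
    streams: dict[int, SpectralStream]  # date -> concatenated stream
    labels: dict[int, np.ndarray]  # date -> hidden class labels
    signature: SpectralStream


def simulate_campaign(config: RunConfig) -> SimulatedCampaign:
    """Generate layout, chemistry, signature and per-date raw streams.

    Per-stage seeds are derived deterministically from ``config.seed`` so
    stages are reproducible in isolation.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(4)
    blocks = generate_layout(config.layout)
    chemistry = generate_chemistry(
        blocks, config.analytes, config.n_dates, int(seeds[0]) % (2**31))
    endmembers = default_endmembers(config.sim.wavelengths)
    signature = make_signature(
        endmembers, config.analytes, config.sim, n_spectra=50,
        seed=int(seeds[1]) % (2**31))
    chem_by_key = {(c.block_id, c.date_index): c for c in chemistry}
    block_seeds = np.random.SeedSequence(int(seeds[2]) % (2**31)).generate_state(
        config.n_dates * len(blocks))
    streams: dict[int, SpectralStream] = {}
    labels: dict[int, np.ndarray] = {}
    theta = np.radians(config.layout.row_azimuth)
    row_dir = (float(np.cos(theta)), float(np.sin(theta)))
    i = 0
    for d in range(config.n_dates):
        parts, lab_parts = [], []
        t0 = 0.0
        for block in blocks:
            stream, labs = generate_stream(
                block,
                chem_by_key[(block.block_id, d)],
                endmembers,
                config.analytes,
                config.sim,
                seed=int(block_seeds[i]) % (2**31),
                block_length=config.layout.block_length,
                row_direction=row_dir,
                t0=t0,
            )
            t0 = float(stream.timestamps[-1]) + 1.0 / config.sim.acquisition_rate
            parts.append(stream)
            lab_parts.append(labs)
            i += 1
        streams[d] = SpectralStream.concatenate(parts)
        labels[d] = np.concatenate(lab_parts)
    return SimulatedCampaign(blocks, chemistry, streams, labels, signature)


def build_dataset(
    campaign: SimulatedCampaign, config: RunConfig
) -> tuple[CalibrationDataset, dict[str, Any]]:
    """Allocate, filter and average the raw streams into the sample table.

    Samples are ordered block-major, date-minor.  Returns the dataset of
    raw (untreated) block-average spectra and the stage bookkeeping
    (spectra in/retained, discarded by allocation, blocks dropped).
    """
    from .spectra_io import allocate_to_blocks

    max_distance = config.layout.block_length / 2.0
    averages: dict[tuple[str, int], np.ndarray] = {}
    info = {"n_spectra_in": 0, "n_retained": 0, "n_discarded_allocation": 0,
            "blocks_dropped": []}
    for d, stream in campaign.streams.items():
        info["n_spectra_in"] += len(stream)
        mapping, discarded = allocate_to_blocks(
            stream, campaign.blocks, max_distance=max_distance)
        info["n_discarded_allocation"] += discarded
        for block in campaign.blocks:
            sub = mapping.get(block.block_id)
            if sub is None or len(sub) == 0:
                info["blocks_dropped"].append((block.block_id, d))
                continue
            retained, report = filter_stream(
                sub, campaign.signature[0],
                threshold=config.filter.threshold,
                centered=config.filter.centered,
                block_id=block.block_id,
            )
            info["n_retained"] += report.n_retained
            try:
                avg = average_block(
                    retained, min_count=config.filter.min_count,
                    block_id=block.block_id)
            except Exception:
                info["blocks_dropped"].append((block.block_id, d))
                continue
            averages[(block.block_id, d)] = avg.values

    if not averages:
        from .filtering import InsufficientSpectraError

        raise InsufficientSpectraError(
            "no block retained enough spectra to form an average "
            f"(threshold {config.filter.threshold}, "
            f"min_count {config.filter.min_count})"
        )
    chem_by_key = {(c.block_id, c.date_index): c for c in campaign.chemistry}
    keys = sorted(averages)  # block-major, date-minor
    X = np.array([averages[k] for k in keys])
    y = {
        a: np.array([chem_by_key[k].analyte(a) for k in keys])
        for a in ANALYTES
    }
    dataset = CalibrationDataset(
        X=X,
        y=y,
        block_ids=[k[0] for k in keys],
        date_indices=np.array([k[1] for k in keys]),
    )
    return dataset, info


def run_all(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config))
    config.to_yaml(out / "config.yaml")
    prov = {"seed": config.seed, "config_hash": manifest.config_hash}

    def timed(stage, fn):
        t = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest.stages.setdefault(stage, {})["seconds"] = round(
            time.perf_counter() - t, 3)
        return result

    campaign = timed("simulate", lambda: simulate_campaign(config))
    write_blocks(campaign.blocks, out / "blocks.csv", prov)
    write_chemistry(campaign.chemistry, out / "chemistry.csv", prov)
    write_stream(campaign.signature, out / "signature.csv", prov)
    for d, stream in campaign.streams.items():
        write_stream(stream, out / f"stream_date{d}.csv", prov)
        pd.DataFrame({"label": campaign.labels[d]}).to_csv(
            out / f"labels_date{d}.csv", index=False)
    manifest.record(
        "simulate",
        n_blocks=len(campaign.blocks),
        n_dates=config.n_dates,
        n_spectra=int(sum(len(s) for s in campaign.streams.values())),
        seconds=manifest.stages["simulate"]["seconds"],
        artifacts={p.name: _hash_file(p) for p in sorted(out.glob("*.csv"))},
    )

    dataset, filter_info = timed(
        "filter", lambda: build_dataset(campaign, config))
    manifest.record("filter", seconds=manifest.stages["filter"]["seconds"],
                    **filter_info)
    dataset_df = pd.DataFrame(
        dataset.X,
        columns=[f"{w:.6g}" for w in config.sim.wavelengths])
    for a in reversed(ANALYTES):
        dataset_df.insert(0, a, dataset.y[a])
    dataset_df.insert(0, "date_index", dataset.date_indices)
    dataset_df.insert(0, "block_id", dataset.block_ids)
    dataset_df.to_csv(out / "dataset.csv", index=False,
                      float_format="%.10g")

    step = float(np.mean(np.diff(config.sim.wavelengths)))
    stats_rows: list[ModelStats] = []
    models = {}
    treated: dict[str, np.ndarray] = {}

    def train_stage():
        for analyte in ANALYTES:
            code = config.treatments.get(analyte, "")
            chain = TreatmentChain.parse(code)
            Xt = apply_chain(chain, dataset.X, step=step)
            flags, _ = detect_outliers(Xt, alpha=config.model.outlier_alpha)
            keep = ~flags
            sub = CalibrationDataset(
                X=Xt[keep],
                y={a: v[keep] for a, v in dataset.y.items()},
                block_ids=[b for b, k in zip(dataset.block_ids, keep) if k],
                date_indices=dataset.date_indices[keep],
            )
            model, stats, cv = train_analyte(
                sub, analyte, treatment=code,
                calibration_fraction=config.model.calibration_fraction,
                n_folds=config.model.n_folds,
                max_lv=config.model.max_lv,
                seed=config.seed,
                r2_mode=config.model.r2_mode,
            )
            treated[analyte] = Xt
            models[analyte] = (model, sub)
            stats_rows.append(stats)
            manifest.record(
                f"train:{analyte}",
                n_samples=int(dataset.n_samples),
                n_outliers=int(flags.sum()),
                n_calibration=stats.n_calibration,
                n_validation=stats.n_validation,
                n_lv=stats.n_lv,
                rmsep=round(stats.rmsep, 4),
                r2_p=round(stats.r2_p, 4),
            )

    timed("train", train_stage)
    stats_df = pd.DataFrame([dataclasses.asdict(s) for s in stats_rows])
    stats_df.to_csv(out / "model_statistics.csv", index=False)
    for analyte, (model, _) in models.items():
        doc = {
            "analyte": analyte,
            "treatment": model.treatment,
            "n_lv": model.n_lv,
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean,
            "coef": model.coef.tolist(),
        }
        (out / f"model_{analyte}.json").write_text(json.dumps(doc))

    def map_stage():
        centroid_by_id = {b.block_id: b.centroid for b in campaign.blocks}
        for analyte in ANALYTES:
            model, _ = models[analyte]
            Xt = treated[analyte]
            per_date = {}
            for d in range(config.n_dates):
                sel = dataset.date_indices == d
                if not np.any(sel):
                    continue
                pts = np.array(
                    [centroid_by_id[b]
                     for b, k in zip(dataset.block_ids, sel) if k])
                yhat = model.predict(Xt[sel])
                per_date[d] = (pts[:, 0], pts[:, 1], yhat)
            maps, scale = render_series(
                per_date,
                cell_size=config.map.cell_size,
                n_levels=config.map.n_levels,
                pad=config.layout.row_spacing,
                mask_distance=config.map.mask_distance,
                analyte=analyte,
            )
            for d, pm in maps.items():
                write_esri_ascii(pm, out / f"map_{analyte}_date{d}.asc")
            manifest.record(
                f"map:{analyte}", n_dates=len(maps),
                scale=[round(scale[0], 4), round(scale[1], 4)])

    timed("map", map_stage)
    manifest.record(
        "artifacts",
        hashes={p.name: _hash_file(p)
                for p in sorted(out.iterdir()) if p.is_file()},
    )
    manifest.to_json(out / "manifest.json")
    return manifest
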