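"""End-to-end pipeline orchestration with config, caching and run manifests.

Stages: preprocess -> band phases -> pairwise coupling inference ->
surrogate significance -> group/region networks -> statistics.  Per-subject
connectivity matrices are cached as TSV keyed by the config hash, so a rerun
with the same configuration resumes from completed work and produces
byte-identical outputs.
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

from . import __version__
from .bayesian import InferenceConfig
from .errors import EcpipeError
from .io_fnirs import (
    ChannelLayout, read_manifest, load_recording, read_connectivity,
    write_connectivity,
)
from .netstats import (
    all_mcds, contrast_ec, correlate_mmse, demographics_tests,
    group_network, subject_region_ec,
)
from .preprocess import PreprocessConfig, preprocess_recording, qc_exclude
from .surrogates import SurrogateConfig, calibrated_connectivity
from .wavelet import BAND_I, BAND_II, FrequencyBand

log = logging.getLogger("ecpipe")


@dataclass
class RunConfig:
    """Fully serializable pipeline run configuration."""

    manifest: str = "manifest.tsv"
    data_dir: str = "."
    out_dir: str = "results"
    fs: float = 10.0
    region_labels: tuple[str, ...] = (
        "LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL"
    )
    region_sizes: tuple[int, ...] = (4, 4, 10, 10, 4, 4)
    bands: tuple[str, ...] = ("I", "II")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    voices: int = 20
    mean_over: str = "all"
    seed: int = 0

    def layout(self) -> ChannelLayout:
        return ChannelLayout(
            tuple(self.region_labels), tuple(self.region_sizes)
        )

    def band_objects(self) -> list[FrequencyBand]:
        table = {"I": BAND_I, "II": BAND_II}
        return [table[b] for b in self.bands]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("inference", InferenceConfig),
            ("surrogate", SurrogateConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("region_labels", "region_sizes", "bands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle of output paths and
    in-memory statistics tables."""
    out = Path(config.out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    chash = config.config_hash()
    layout = config.layout()

    manifest = read_manifest(Path(config.data_dir) / config.manifest)
    log.info("loaded manifest: %d subjects", len(manifest))

    despike_fracs: dict[str, np.ndarray] = {}
    matrices: dict[tuple[str, str, str], object] = {}
    states = ("sitting", "standing")
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        for state in states:
            rel = row.get(f"path_{state}")
            if not isinstance(rel, str):
                continue
            path = Path(config.data_dir) / rel
            if not path.exists():
                raise EcpipeError(
                    f"missing recording for subject {sid} ({state}): {path}"
                )
            cached_all = all(
                _cache_path(out, sid, state, b, chash).exists()
                for b in config.bands
            )
            if cached_all:
                for b in config.bands:
                    matrices[(sid, state, b)] = read_connectivity(
                        _cache_path(out, sid, state, b, chash)
                    )
                log.info("resumed %s/%s from cache", sid, state)
                continue
            rec = load_recording(
                path, layout, fs=config.fs, subject_id=sid,
                group=row["group"], state=state,
            )
            rec, frac = preprocess_recording(rec, config.preprocess)
            worst = despike_fracs.get(sid)
            if worst is None or frac.max() > worst.max():
                despike_fracs[sid] = frac
            for band in config.band_objects():
                try:
                    cm = calibrated_connectivity(
                        rec.data, rec.fs, band,
                        inference=config.inference,
                        surrogate=dataclasses.replace(
                            config.surrogate, seed=config.seed
                        ),
                        voices=config.voices,
                        subject_id=sid, state=state,
                    )
                except EcpipeError as exc:
                    raise EcpipeError(
                        f"stage failed for subject {sid}, state {state}, "
                        f"band {band.name}: {exc}"
                    ) from exc
                cpath = _cache_path(out, sid, state, band.name, chash)
                write_connectivity(cm, cpath)
                # downstream stages always consume the cached (rounded)
                # representation so reruns are byte-identical
                matrices[(sid, state, band.name)] = read_connectivity(cpath)
            log.info("computed %s/%s", sid, state)

    qc = (
        qc_exclude(despike_fracs) if despike_fracs
        else pd.DataFrame(columns=["subject_id", "excluded"])
    )
    qc.to_csv(out / "stats" / "qc_report.tsv", sep="\t", index=False)

    groups = sorted(manifest["group"].unique())
    region_ecs: dict[tuple[str, str, str], list] = {}
    subj_groups: dict[str, str] = dict(
        zip(manifest["subject_id"], manifest["group"])
    )
    group_nets = {}
    mcd_tables = []
    for band_name in config.bands:
        for state in states:
            for grp in groups:
                cms = [
                    cm for (sid, st, b), cm in matrices.items()
                    if st == state and b == band_name
                    and subj_groups[sid] == grp
                ]
                key = (grp, state, band_name)
                if len(cms) >= 2:
                    gn = group_network(cms, mean_over=config.mean_over)
                    gn.group = grp
                    group_nets[key] = gn
                    np.savetxt(
                        out / "matrices" /
                        f"group_{grp}_{state}_{band_name}.tsv",
                        gn.mean_strengths, delimiter="\t", fmt="%.6g",
                    )
                    for res in all_mcds(cms, layout):
                        mcd_tables.append(
                            dict(group=grp, state=state, band=band_name,
                                 region_1=res.region_1,
                                 region_2=res.region_2,
                                 direction=res.direction, p=res.p_value,
                                 n_votes=res.n_votes,
                                 votes_r1_to_r2=res.votes_r1_to_r2)
                        )
                region_ecs[key] = [
                    subject_region_ec(cm, layout) for cm in cms
                ]
    mcd_df = pd.DataFrame(mcd_tables)
    mcd_df.to_csv(out / "stats" / "mcd.tsv", sep="\t", index=False)

    contrasts = []
    for band_name in config.bands:
        # posture contrast within each group
        for grp in groups:
            a = region_ecs.get((grp, "sitting", band_name), [])
            b = region_ecs.get((grp, "standing", band_name), [])
            if len(a) >= 2 and len(b) >= 2:
                df = contrast_ec(a, b, "sitting", "standing")
                df.insert(0, "contrast", f"{grp}: sitting vs standing")
                df.insert(1, "band", band_name)
                contrasts.append(df)
        # group contrast within each state
        if len(groups) == 2:
            for state in states:
                a = region_ecs.get((groups[0], state, band_name), [])
                b = region_ecs.get((groups[1], state, band_name), [])
                if len(a) >= 2 and len(b) >= 2:
                    df = contrast_ec(a, b, groups[0], groups[1])
                    df.insert(
                        0, "contrast",
                        f"{state}: {groups[0]} vs {groups[1]}",
                    )
                    df.insert(1, "band", band_name)
                    contrasts.append(df)
    contrast_df = (
        pd.concat(contrasts, ignore_index=True) if contrasts
        else pd.DataFrame()
    )
    contrast_df.to_csv(out / "stats" / "contrasts.tsv", sep="\t", index=False)

    corr_tables = []
    elderly = manifest[manifest["group"] == "elderly"]
    if len(elderly) >= 4:
        sid_order = {s: i for i, s in enumerate(manifest["subject_id"])}
        for band_name in config.bands:
            for state in states:
                nets = region_ecs.get(("elderly", state, band_name), [])
                if len(nets) < 4:
                    continue
                mmse = np.array([
                    float(
                        manifest.loc[
                            manifest["subject_id"] == n.subject_id, "mmse"
                        ].iloc[0]
                    )
                    for n in nets
                ])
                df = correlate_mmse(nets, mmse)
                df.insert(0, "state", state)
                df.insert(1, "band", band_name)
                corr_tables.append(df)
    corr_df = (
        pd.concat(corr_tables, ignore_index=True) if corr_tables
        else pd.DataFrame()
    )
    corr_df.to_csv(out / "stats" / "mmse_correlations.tsv", sep="\t",
                   index=False)

    demo_df = (
        demographics_tests(manifest) if len(groups) == 2 else pd.DataFrame()
    )
    demo_df.to_csv(out / "stats" / "demographics.tsv", sep="\t", index=False)

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "versions": {
            "ecpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": int(len(manifest)),
        "n_matrices": len(matrices),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=1, sort_keys=True, default=list)
    )
    return {
        "matrices": matrices,
        "group_networks": group_nets,
        "region_ecs": region_ecs,
        "contrasts": contrast_df,
        "mcd": mcd_df,
        "mmse_correlations": corr_df,
        "demographics": demo_df,
        "qc": qc,
        "out_dir": out,
    }


def _cache_path(out: Path, sid: str, state: str, band: str,
                chash: str) -> Path:
    return out / "matrices" / f"{sid}_{state}_{band}.{chash}.tsv"
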