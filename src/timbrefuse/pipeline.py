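"""End-to-end orchestration: synthesis/loading → QC → scaling → statistics
→ acoustic features → fusion models, with one master seed and a manifest.

Each stage writes its outputs as plain files inside the run directory, and
the next stage reads those files, so any stage can be re-run from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ATTRIBUTES, RatingMatrix
from .features import CANONICAL_FEATURES, features_frame
from .model import run_grouped_models
from .perception import (attribute_correlations, category_frequencies,
                         mdpref_map, one_way_anova, snk_groups, two_way_anova)
from .qc import validity_filter
from .scaling import fit_all_attributes, scales_frame
from .synth import LatentPerceptModel, build_stimulus_set, loudness_normalize, synth_ratings

logger = logging.getLogger("timbrefuse")

_STAGES = ("synth", "qc", "scaling", "stats", "features", "models")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (a design block) or ``inputs`` (paths to
    ratings/metadata/audio files) must be provided.
    """

    synthetic: dict | None = None     # {design, n_raters, duration_s, ...}
    inputs: dict | None = None        # {ratings, metadata, audio_dir}
    k_sd: float = 1.5
    extreme: str = "clip"             # scaling 0/1-proportion handling
    alpha: float = 0.05
    model_kinds: tuple = ("linear_lasso", "random_forest", "mlp")
    folds: int = 4
    model_config: dict = field(default_factory=lambda: {"refit_ols": True})
    coef_threshold: float = 4.0
    target_rms: float = 0.1
    write_audio: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(**raw)


def _stage_seeds(master_seed: int) -> dict:
    """Derive one independent sub-seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(len(_STAGES)) % (2 ** 31 - 1)
    return {stage: int(s) for stage, s in zip(_STAGES, states)}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write stage outputs and a manifest, return the manifest.

    Any stage failure aborts with the stage name in the exception; files
    written by completed stages are retained.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    from . import __version__

    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": seeds, "stages": {}}

    stage = "synth"
    try:
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            stimuli, metadata = build_stimulus_set(
                config=syn.get("design"), seed=seeds["synth"],
                duration_s=syn.get("duration_s", 1.0),
                sample_rate=syn.get("sample_rate", 44100))
            stimuli = [loudness_normalize(s, config.target_rms)
                       for s in stimuli]
            latent = syn.get("latent") or LatentPerceptModel()
            ratings = synth_ratings(latent, metadata,
                                    n_raters=syn.get("n_raters", 32),
                                    seed=seeds["synth"])
            metadata.to_csv(out / "metadata.csv", index=False)
            ratings.to_csv(out / "ratings.csv")
            if config.write_audio:
                wav_dir = out / "wav"
                wav_dir.mkdir(exist_ok=True)
                for s in stimuli:
                    s.write_wav(wav_dir / f"{s.stimulus_id}.wav")
        else:
            paths = config.inputs
            for key in ("ratings", "metadata"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"missing input path for {key!r}: "
                        f"{paths.get(key)}")
            ratings = RatingMatrix.from_csv(paths["ratings"])
            metadata = pd.read_csv(paths["metadata"])
            stimuli = None
            if paths.get("audio_dir"):
                from .containers import AudioStimulus

                stimuli = [AudioStimulus.read_wav(p)
                           for p in sorted(Path(paths["audio_dir"]).glob("*.wav"))]
        manifest["stages"]["synth"] = {
            "n_stimuli": len(metadata), "n_raters": len(ratings.raters),
            "n_attributes": len(ratings.attributes),
            "per_culture": metadata["culture"].value_counts().to_dict()}
        logger.info("synth: %d stimuli, %d raters", len(metadata),
                    len(ratings.raters))

        stage = "qc"
        cleaned, report = validity_filter(ratings, k_sd=config.k_sd)
        cleaned.to_csv(out / "ratings_cleaned.csv")
        report.to_json(out / "qc.json")
        manifest["stages"]["qc"] = {"alpha": report.alpha,
                                    "n_removed": report.n_removed}

        stage = "scaling"
        scales = fit_all_attributes(cleaned, extreme=config.extreme)
        sf = scales_frame(scales)
        sf.to_csv(out / "scales.csv", index=False)
        bounds = {a: list(map(float, s.boundaries))
                  for a, s in scales.items()}
        (out / "boundaries.json").write_text(json.dumps(bounds, indent=2))
        manifest["stages"]["scaling"] = {
            "attributes": sorted(scales),
            "flagged": {a: s.flagged for a, s in scales.items()
                        if s.flagged}}

        stage = "stats"
        wide = sf.pivot(index="stimulus_id", columns="attribute",
                        values="scale_cat")
        meta_idx = metadata.set_index("stimulus_id").loc[wide.index]
        stats_out: dict = {}
        freq = category_frequencies(wide["fusion"],
                                    meta_idx["envelope_class"])
        freq.to_csv(out / "fusion_category_frequencies.csv", index=False)
        for attr in ATTRIBUTES:
            if attr not in wide.columns:
                continue
            ow = one_way_anova(wide[attr], meta_idx["envelope_class"])
            full, refit = two_way_anova(wide[attr],
                                        meta_idx["envelope_class"],
                                        meta_idx["culture"],
                                        alpha=config.alpha)
            subsets = snk_groups(wide[attr], meta_idx["envelope_class"],
                                 alpha=config.alpha)
            stats_out[attr] = {
                "class_means": wide[attr].groupby(
                    meta_idx["envelope_class"]).mean().to_dict(),
                "one_way": {"F": ow.f("factor"), "p": ow.p("factor"),
                            "df": [int(ow.terms.loc['factor', 'df']),
                                   ow.residual_df]},
                "two_way_interaction_p": full.p("envelope:culture"),
                "two_way_refit": (
                    None if refit is None else
                    {t: {"F": refit.f(t), "p": refit.p(t)}
                     for t in refit.terms.index}),
                "snk_subsets": subsets,
            }
        corr, pvals = attribute_correlations(wide)
        corr.to_csv(out / "attribute_correlations.csv")
        pmap = mdpref_map(wide, metadata)
        pmap.loadings.to_csv(out / "mdpref_loadings.csv")
        pmap.stimulus_coords.to_csv(out / "mdpref_coords.csv")
        if not pmap.centroids.empty:
            pmap.centroids.to_csv(out / "mdpref_centroids.csv", index=False)
        stats_out["correlations"] = corr.to_dict()
        stats_out["mdpref_loadings"] = pmap.loadings.to_dict()
        stats_out["mdpref_variance_explained"] = [
            float(v) for v in pmap.variance_explained]
        (out / "stats.json").write_text(json.dumps(stats_out, indent=2))
        manifest["stages"]["stats"] = {
            "correlation_fusion_segregation":
                float(corr.loc["fusion", "segregation"])
                if "segregation" in corr else None}

        stage = "features"
        if stimuli is None:
            raise ValueError("no audio available for feature extraction")
        feats = features_frame(stimuli)
        feats.to_csv(out / "features.csv")
        manifest["stages"]["features"] = {
            "n_features": len(CANONICAL_FEATURES),
            "n_stimuli": len(feats)}

        stage = "models"
        target = wide["fusion"].loc[feats.index]
        grouped = run_grouped_models(
            feats, target, metadata, kinds=config.model_kinds,
            k=config.folds, config=config.model_config,
            seed=seeds["models"], coef_threshold=config.coef_threshold)
        grouped["table"].to_csv(out / "model_r2_grid.csv")
        eq_text = "\n".join(eq.render()
                            for eq in grouped["equations"].values())
        (out / "fusion_equations.txt").write_text(eq_text + "\n")
        results_json = {
            f"{label}/{kind}": {k2: v2 for k2, v2 in entry.items()}
            for (label, kind), entry in grouped["results"].items()}
        (out / "models.json").write_text(json.dumps(results_json, indent=2))
        manifest["stages"]["models"] = {
            "n_cells": len(grouped["results"]),
            "grid": grouped["table"].to_dict()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
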