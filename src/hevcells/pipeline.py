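"""End-to-end orchestration: image in, consensus segmentation (and
optionally an evaluation report) out.

Stages: crop -> colour deconvolution -> tissue mask -> nuclear seeds ->
watershed v-cells -> 63-feature table -> clustering ensemble ->
diversity selection -> consensus -> evaluation against a gold standard
when one is supplied.  Errors carry the stage name; artefacts produced
before a failure are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation, stains
from .clustering import Ensemble, generate_ensemble, _rerun
from .config import PipelineConfig
from .consensus import (ConsensusResult, coassociation, eac_consensus,
                        render_consensus, voting_consensus)
from .errors import StageError
from .evaluation import EvalReport, evaluate, transfer_gold
from .features import build_feature_table, standardise
from .segmentation import VCellMap
from .selection import SelectionConfig, select_ensemble


@dataclass
class PipelineResult:
    """Bundle of everything one run produced."""

    config: PipelineConfig
    crop_offset: tuple[int, int]
    stain_image: np.ndarray
    vcells: VCellMap
    features: pd.DataFrame
    ensemble: Ensemble
    selected: Ensemble
    selection_report: list
    consensus: dict[str, ConsensusResult]
    evaluation: dict[str, EvalReport] = field(default_factory=dict)
    gold_vcells: np.ndarray | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # tag with the failing stage
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    gold: np.ndarray | None = None,
) -> PipelineResult:
    """Run every stage on an 8-bit RGB image (arrays in, results out)."""
    vectors = config.vectors()

    if config.crop:
        cropped, offset = _stage("crop")(segmentation.crop_to_tissue)(image)
        if gold is not None:
            gold = gold[offset[0]:offset[0] + cropped.shape[0],
                        offset[1]:offset[1] + cropped.shape[1]]
    else:
        cropped, offset = image, (0, 0)

    stain = _stage("deconvolve")(stains.deconvolve)(cropped, vectors)
    vcells = _stage("segment")(segmentation.segment)(
        stain, h=config.h, e=config.e, watershed_mode=config.watershed_mode)
    table = _stage("features")(build_feature_table)(vcells, stain)
    x = standardise(table)

    ensemble = _stage("ensemble")(generate_ensemble)(
        x, k=config.k, rng_seed=config.rng_seed,
        n_kmeans=config.n_kmeans, n_em=config.n_em)

    rng = np.random.default_rng(config.rng_seed + 1)

    def regenerate(part, attempt):
        return _rerun(part.algorithm, part.params, x, config.k, rng)

    selected, report = _stage("selection")(select_ensemble)(
        ensemble, SelectionConfig(config.d1, config.d2), regenerate)

    consensus: dict[str, ConsensusResult] = {}
    methods = (("eac", "voting") if config.consensus_method == "both"
               else (config.consensus_method,))
    for method in methods:
        if method == "eac":
            consensus["eac"] = _stage("consensus")(
                lambda: eac_consensus(coassociation(selected)))()
        else:
            consensus["voting"] = _stage("consensus")(
                lambda: voting_consensus(selected, vcells, original=ensemble))()

    result = PipelineResult(config, offset, stain, vcells, table,
                            ensemble, selected, report, consensus)
    if gold is not None:
        gv = _stage("evaluate")(transfer_gold)(gold, vcells)
        result.gold_vcells = gv
        for method, cr in consensus.items():
            result.evaluation[method] = _stage("evaluate")(evaluate)(
                cr.partition, gv, vcells)
    return result


def write_artefacts(result: PipelineResult, outdir: str | Path):
    """Persist the standard artefact bundle of one run."""
    import tifffile
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.save(outdir / "config.yaml")
    tifffile.imwrite(outdir / "stain_image.tif", result.stain_image)
    tifffile.imwrite(outdir / "vcells.tif",
                     result.vcells.labels.astype(np.uint16))
    tifffile.imwrite(outdir / "nuclei.tif",
                     result.vcells.nuclei.astype(np.uint16))
    result.features.to_csv(outdir / "features.csv")

    lm = result.selected.labels_matrix()
    cols = [f"{p.algorithm}_{i}" for i, p in enumerate(result.selected)]
    pd.DataFrame(lm, columns=cols,
                 index=pd.RangeIndex(1, lm.shape[0] + 1, name="vcell_id")
                 ).to_csv(outdir / "ensemble.csv")
    provenance = [{"algorithm": p.algorithm, "params": p.params, "seed": p.seed}
                  for p in result.selected]
    (outdir / "ensemble_provenance.json").write_text(json.dumps(provenance, indent=2))
    (outdir / "selection_report.json").write_text(
        json.dumps(result.selection_report, indent=2))

    for method, cr in result.consensus.items():
        pd.DataFrame({"vcell_id": np.arange(1, len(cr.partition.labels) + 1),
                      "class": cr.partition.labels}
                     ).to_csv(outdir / f"consensus_{method}.csv", index=False)
        Image.fromarray(render_consensus(cr, result.vcells)).save(
            outdir / f"consensus_{method}.png")
    if result.evaluation:
        (outdir / "evaluation.json").write_text(json.dumps(
            {m: r.as_dict() for m, r in result.evaluation.items()}, indent=2))
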