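"""End-to-end orchestration: features → partition → design → encode → fit → evaluate.

Two entry points:

* :func:`run_synthetic_study` — the fully synthetic study: generate a toy
  globule, partition it, design a balanced library, simulate a plate screen
  with epistasis confined to one structural class, fit all four models and
  report per-class predictability. One global seed fans out to per-stage
  child seeds.
* :func:`run_pipeline` — the real-data path driven by a YAML/dict config
  (structure + screen CSV + optional MSA).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignConfig, blosum62_scorer, design_library, library_to_frame
from .encoding import random_projection_embedder
from .evaluation import EvaluationReport, normalize_screen, predictability_report, read_screen_csv
from .models import MODEL_NAMES, ModelContext
from .partitioning import assign_bins, binarize_profile
from .potts import MSA, fit_potts
from .structure import build_profile, read_structure
from .synthetic import (
    LandscapeParams,
    conserved_potts_model,
    generate_activity_landscape,
    generate_potts_msa,
    generate_toy_structure,
    simulate_screen,
)

__all__ = ["run_synthetic_study", "run_pipeline", "child_seeds"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out to independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_synthetic_study(
    n_residues: int = 200,
    n_per_bin: int = 100,
    hard_characteristic: str = "buried",
    models: Sequence[str] = MODEL_NAMES,
    characteristics: Sequence[str] | None = None,
    landscape: LandscapeParams | None = None,
    folds: int = 10,
    seed: int = 0,
    n_msa: int = 200,
    n_coupled_pairs: int = 10,
    potts_max_iter: int = 50,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the whole synthetic study; returns all stage artifacts in a dict.

    The defaults mirror the study conditions the package emulates: a
    200-residue enzyme, 100 variants per factorial bin (1,600 total, matching
    the scale of a few thousand screened variants), up to 8 mutations per
    variant, triplicate plates with two blanks, 10-fold cross-validation.
    """
    landscape = landscape or LandscapeParams()
    seeds = child_seeds(seed, 6)

    structure, intended = generate_toy_structure(n_residues, seed=seeds[0])
    active_sites = list(intended.attrs["active_sites"])
    profile = build_profile(structure, active_sites)
    binary = binarize_profile(profile)
    partition = assign_bins(binary)
    reference = structure.sequence

    config = DesignConfig(
        n_per_bin=n_per_bin,
        scorer=blosum62_scorer(reference),
        seed=seeds[1],
        cap_to_capacity=True,
        min_bin_positions=8,  # keep the mutation-count mix comparable across classes
    )
    library = design_library(partition, reference, config)

    truth = generate_activity_landscape(
        partition, hard_characteristic, params=landscape, seed=seeds[2]
    )

    potts = None
    if "augmented_potts" in models:
        hard_pos = sorted(partition.positive_positions(hard_characteristic))
        rng = np.random.default_rng(seeds[3])
        pairs = set()
        while len(pairs) < min(n_coupled_pairs, len(hard_pos) // 2):
            i, j = sorted(rng.choice(len(hard_pos), size=2, replace=False))
            if i != j:
                pairs.add((hard_pos[i] - 1, hard_pos[j] - 1))
        generating = conserved_potts_model(reference, sorted(pairs), seed=seeds[3])
        msa = generate_potts_msa(generating, n_sequences=n_msa, burn_in=100, seed=seeds[3])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # early-stopped fit is expected at this scale
            potts = fit_potts(msa, max_iter=potts_max_iter)
        truth.potts = generating

    screen = simulate_screen(library, truth, seed=seeds[4])
    records, lods = normalize_screen(screen)

    context = ModelContext(
        reference=reference,
        potts=potts,
        embedder=random_projection_embedder(reference, dim=1024, seed=0),
    )
    report = predictability_report(
        records,
        binary,
        model_names=models,
        context=context,
        characteristics=tuple(characteristics) if characteristics else (hard_characteristic,),
        k=folds,
        seed=seeds[5],
    )
    result = {
        "structure": structure,
        "intended_labels": intended,
        "profile": profile,
        "binary": binary,
        "partition": partition,
        "reference": reference,
        "library": library,
        "truth": truth,
        "screen": screen,
        "records": records,
        "lods": lods,
        "potts": potts,
        "context": context,
        "report": report,
        "seeds": seeds,
    }
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir), seed)
    return result


def _write_artifacts(result: dict, out_dir: Path, seed: int) -> None:
    from .structure import write_structure

    out_dir.mkdir(parents=True, exist_ok=True)
    write_structure(result["structure"], out_dir / "structure.pdb")
    result["profile"].to_csv(out_dir / "profile.csv")
    result["partition"].to_csv(out_dir / "partition.csv")
    result["partition"].save_summary(out_dir / "partition_summary.json")
    library_to_frame(result["library"], result["reference"]).to_csv(
        out_dir / "library.csv", index=False
    )
    result["screen"].to_csv(out_dir / "screen_raw.csv", index=False)
    result["report"].to_json(out_dir / "report.json")
    result["report"].scores_frame().to_csv(out_dir / "fold_scores.csv", index=False)
    (out_dir / "run_meta.json").write_text(
        json.dumps({"seed": seed, "lod_median": float(np.median(list(result["lods"].values())))})
    )


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> EvaluationReport:
    """Real-data path: structure + screen CSV (+ optional MSA) → report."""
    required = {"structure", "active_sites", "data"}
    missing = required - set(config)
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    models = tuple(config.get("models", ("residue_agnostic", "pls")))
    for path_key in ("structure", "data", "msa"):
        if path_key in config and not Path(config[path_key]).exists():
            raise FileNotFoundError(f"{path_key}: {config[path_key]}")
    if "augmented_potts" in models and "msa" not in config:
        raise ValueError("augmented_potts requested but no MSA configured")

    structure = read_structure(
        config["structure"], chain=config.get("chain"), offset=int(config.get("offset", 0))
    )
    profile = build_profile(structure, [int(p) for p in config["active_sites"]])
    binary = binarize_profile(profile)

    reference = config.get("reference_sequence") or structure.sequence
    records, _lods = normalize_screen(read_screen_csv(config["data"]))

    potts = None
    if "augmented_potts" in models:
        potts = fit_potts(
            MSA.from_fasta(config["msa"]),
            gap_cutoff=float(config.get("gap_cutoff", 1.0)),
            max_iter=int(config.get("potts_max_iter", 500)),
        )
    embedder = None
    if "embedding" in models:
        embedder = random_projection_embedder(reference, dim=int(config.get("embedding_dim", 1024)))
    context = ModelContext(
        reference=reference,
        potts=potts,
        embedder=embedder,
        alpha=float(config.get("alpha", 0.1)),
        n_components=int(config.get("n_components", 20)),
    )
    report = predictability_report(
        records,
        binary,
        model_names=models,
        context=context,
        k=int(config.get("folds", 10)),
        seed=int(config.get("seed", 0)),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        profile.to_csv(out / "profile.csv")
        assign_bins(binary).to_csv(out / "partition.csv")
        report.to_json(out / "report.json")
        report.scores_frame().to_csv(out / "fold_scores.csv", index=False)
    return report
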