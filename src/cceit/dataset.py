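"""Training-set orchestration: phantoms -> forward simulation -> samples.

Each dataset sample pairs a simulated measurement frame (2 x 240 real/
imaginary stack) with a 64 x 64 conductivity target normalised to [0, 1]
over the head support, plus a condition label (healthy / hemorrhagic /
ischemic, drawn uniformly).  Half of the samples come from the
constraint-table sampler, half from Gaussian perturbation of a frozen set
of base geometries (standing in for manually fitted reference models).

Every sample is regenerable from its seed record alone: child random
streams are derived from the root seed by spawn keys, so generation order
and parallelism cannot change a sample's content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import Grid
from .phantom import (RegionPropertyPriors, apply_stroke, assign_region_properties,
                      build_healthy_phantom, sample_stroke,
                      DegeneratePhantomError, StrokeInsertionError)
from .sampler import (ConstraintTables, SamplingError, load_tables,
                      perturb_geometry, sample_geometry)
from .solver import (MeasurementFrame, SensorModel, SolverError,
                     add_measurement_noise, field_from_phantom, measure_frame)

__all__ = [
    "CONDITIONS",
    "DatasetConfig",
    "SampleSet",
    "draw_condition",
    "draw_conditions",
    "build_dataset",
    "split_train_test",
    "save_hdf5",
    "load_hdf5",
]

CONDITIONS = ("healthy", "hemorrhagic", "ischemic")


def draw_condition(rng_seed=0) -> str:
    """One patient condition, uniform over the three classes."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return CONDITIONS[rng.integers(0, len(CONDITIONS))]


def draw_conditions(n: int, rng_seed=0) -> np.ndarray:
    """Vector of n condition indices (0 healthy, 1 hemorrhagic, 2 ischemic)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return rng.integers(0, len(CONDITIONS), size=n)


@dataclass(frozen=True)
class DatasetConfig:
    image_n: int = 64
    solver_n: int = 64
    snr_db: float = np.inf        # noise stored in the dataset; inf = clean
    n_bases: int = 50             # frozen base geometries for the perturbation mode
    perturb_sd: float = 0.05
    sampling_law: str = "truncnorm"


@dataclass
class SampleSet:
    """A bundle of generated samples plus its manifest."""

    inputs: np.ndarray            # (N, 2, M) raw re/im capacitance stacks
    targets: np.ndarray           # (N, image_n, image_n) in [0, 1]
    labels: np.ndarray            # (N,) condition index into CONDITIONS
    approaches: np.ndarray        # (N,) 0 = constraint-based, 1 = perturbation-based
    seeds: np.ndarray             # (N, 3) (root_seed, sample_index, retry)
    manifest: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.inputs)

    def subset(self, idx) -> "SampleSet":
        idx = np.asarray(idx)
        return SampleSet(self.inputs[idx], self.targets[idx], self.labels[idx],
                         self.approaches[idx], self.seeds[idx], dict(self.manifest))


def _normalized_target(phantom) -> np.ndarray:
    """Min-max normalise the conductivity map over the head support."""
    support = phantom.region_map > 0
    sig = phantom.sigma_map
    lo, hi = sig[support].min(), sig[support].max()
    out = np.zeros_like(sig, dtype=np.float32)
    if hi > lo:
        out[support] = (sig[support] - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def generate_sample(seed_triplet, tables: ConstraintTables, sensor: SensorModel,
                    config: DatasetConfig, priors: RegionPropertyPriors,
                    bases: Optional[list] = None):
    """Generate one sample deterministically from its seed record.

    Returns ``(input_stack, target, condition_index, approach)``.
    Raises the underlying generation error on failure (the build loop
    retries with a fresh seed record).
    """
    root, index, retry = (int(v) for v in seed_triplet)
    rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(0, index, retry)))
    cond_idx = int(rng.integers(0, len(CONDITIONS)))
    condition = CONDITIONS[cond_idx]

    if bases is not None:
        base = bases[int(rng.integers(0, len(bases)))]
        geom = perturb_geometry(base, config.perturb_sd, rng, tables=tables)
        approach = 1
    else:
        geom = sample_geometry(tables, rng, law=config.sampling_law)
        approach = 0

    props = assign_region_properties(priors, rng)
    stroke = None
    if condition != "healthy":
        stroke = sample_stroke(geom, props, condition, rng)

    image_grid = Grid(tables.image_extent, config.image_n)
    solver_grid = sensor.default_grid(config.solver_n)
    ph_img = build_healthy_phantom(geom, props, image_grid)
    ph_sol = build_healthy_phantom(geom, props, solver_grid)
    if stroke is not None:
        ph_img = apply_stroke(ph_img, stroke)
        ph_sol = apply_stroke(ph_sol, stroke)

    frame = measure_frame(field_from_phantom(ph_sol, sensor), sensor)
    if np.isfinite(config.snr_db):
        frame = add_measurement_noise(frame, config.snr_db, rng)
    return frame.as_real_input(), _normalized_target(ph_img), cond_idx, approach


def make_base_geometries(tables: ConstraintTables, config: DatasetConfig,
                         root_seed: int) -> list:
    """The frozen base models used by the perturbation generator."""
    bases = []
    for k in range(config.n_bases):
        rng = np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(1, k)))
        bases.append(sample_geometry(tables, rng, law=config.sampling_law))
    return bases


def build_dataset(n_constraint: int, n_perturb: int, rng_seed: int = 0,
                  tables: Optional[ConstraintTables] = None,
                  sensor: Optional[SensorModel] = None,
                  config: DatasetConfig = DatasetConfig(),
                  priors: RegionPropertyPriors = RegionPropertyPriors(),
                  progress: bool = False) -> SampleSet:
    """Simulate ``n_constraint`` constraint-based plus ``n_perturb``
    perturbation-based samples.

    Per-sample failures (rejection budgets, degenerate rasters, solver
    errors) are retried with a bumped retry counter and tallied in the
    manifest; they do not abort the build.
    """
    if n_constraint < 0 or n_perturb < 0 or n_constraint + n_perturb < 1:
        raise ValueError("need at least one sample")
    tables = tables or load_tables()
    sensor = sensor or SensorModel()
    bases = make_base_geometries(tables, config, rng_seed) if n_perturb else None

    n_total = n_constraint + n_perturb
    inputs, targets, labels, approaches, seeds = [], [], [], [], []
    failures = 0
    iterator = range(n_total)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="simulate")
    for i in iterator:
        use_bases = bases if i >= n_constraint else None
        for retry in range(20):
            triplet = (rng_seed, i, retry)
            try:
                x, y, cond, appr = generate_sample(triplet, tables, sensor,
                                                   config, priors, use_bases)
                break
            except (SamplingError, StrokeInsertionError, DegeneratePhantomError,
                    SolverError):
                failures += 1
        else:
            raise RuntimeError(f"sample {i} failed 20 consecutive generation attempts")
        inputs.append(x)
        targets.append(y)
        labels.append(cond)
        approaches.append(appr)
        seeds.append(triplet)

    labels = np.asarray(labels, np.int8)
    manifest = {
        "root_seed": int(rng_seed),
        "n_constraint": int(n_constraint),
        "n_perturb": int(n_perturb),
        "condition_counts": {c: int((labels == k).sum())
                             for k, c in enumerate(CONDITIONS)},
        "generation_failures": int(failures),
        "config": {k: (v if np.isfinite(v) else "inf") if isinstance(v, float) else v
                   for k, v in asdict(config).items()},
        "image_extent_mm": tables.image_extent,
        "standardization": "per-channel z-scoring fitted on the training split "
                           "at training time",
    }
    return SampleSet(np.asarray(inputs), np.asarray(targets, np.float32), labels,
                     np.asarray(approaches, np.int8), np.asarray(seeds, np.int64),
                     manifest)


def split_train_test(samples: SampleSet, ratio: float = 0.75,
                     rng_seed: int = 0):
    """Random disjoint split at the given train fraction (exact to +-1)."""
    if not (0.0 < ratio < 1.0):
        raise ValueError("split ratio must be in (0, 1)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = len(samples)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    train, test = samples.subset(order[:n_train]), samples.subset(order[n_train:])
    train.manifest["split"] = {"role": "train", "ratio": ratio, "n": n_train}
    test.manifest["split"] = {"role": "test", "ratio": ratio, "n": n - n_train}
    return train, test


# ---------------------------------------------------------------------------
# persistence

def save_hdf5(samples: SampleSet, path) -> None:
    """Write a sample set to an HDF5 container (+ JSON manifest sidecar)."""
    import h5py
    from pathlib import Path

    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=samples.inputs, compression="gzip")
        fh.create_dataset("targets", data=samples.targets, compression="gzip")
        fh.create_dataset("labels", data=samples.labels)
        fh.create_dataset("approaches", data=samples.approaches)
        fh.create_dataset("seeds", data=samples.seeds)
        fh.attrs["manifest"] = json.dumps(samples.manifest)
    Path(str(path) + ".manifest.json").write_text(json.dumps(samples.manifest, indent=2))


def load_hdf5(path) -> SampleSet:
    import h5py

    with h5py.File(path, "r") as fh:
        return SampleSet(fh["inputs"][:], fh["targets"][:], fh["labels"][:],
                         fh["approaches"][:], fh["seeds"][:],
                         json.loads(fh.attrs["manifest"]))
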