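"""Synthetic decoy ensembles with planted class structure.

Real decoy sets for a target protein come from many prediction servers and
carry two levels of structure: a handful of distinct backbone
conformations (classes) and per-decoy noise within each class.  The
generator emulates exactly that two-level structure so every stage of the
pipeline — selection, partitioning, discriminant reduction, sampling,
refinement — is testable without any external download:

* a reference backbone: ideal-helix Cα segments (3.8 Å steps) joined by
  random axis turns, self-avoiding;
* ``n_classes`` class centers: the reference deformed along distinct
  smooth low-frequency sinusoidal displacement fields of the chain
  (concerted movements, the kind of difference a discriminant direction
  should capture);
* templates: class center + isotropic per-atom Gaussian noise.

Energies are assigned by a configurable energy model; a test mode adds a
per-class energy offset so that the energy-space classes provably coincide
with the structural classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .energy import SurrogateEnergy
from .lda import ClassPartition, TemplateEnsemble
from .structures import CaTrace, flatten

__all__ = ["SyntheticSpec", "make_reference_backbone", "make_template_ensemble"]

STEP = 3.8          # consecutive Cα-Cα distance, Å
TWIST = np.deg2rad(100.0)   # helical twist per residue
CONE = np.arccos(1.5 / STEP)  # bond-to-axis angle giving a 1.5 Å rise
CLASH_DISTANCE = 3.5  # minimum allowed nonbonded (|i-j| >= 3) distance, Å


@dataclass
class SyntheticSpec:
    """Ensemble recipe: geometry, class structure, noise, and seed.

    ``class_shift_scale`` is the amplitude (Å) of the low-frequency
    deformation separating class centers; ``within_noise`` is the per-atom
    Gaussian standard deviation (Å) inside a class.  Defaults (3.0 / 0.5 Å)
    give clearly separated classes with realistic within-class scatter.
    """

    residue_count: int = 120
    n_classes: int = 4
    templates_per_class: int = 15
    class_shift_scale: float = 3.0
    within_noise: float = 0.5
    seed: int = 0
    class_energy_offset: float = 0.0  # > 0: test mode, classes separable by energy

    def __post_init__(self) -> None:
        if self.residue_count < 10:
            raise ValueError("residue_count must be >= 10")
        if not 2 <= self.n_classes <= 10:
            raise ValueError("n_classes must be in [2, 10]")
        if self.templates_per_class < 2:
            raise ValueError("templates_per_class must be >= 2")


def _helix_directions(n_steps: int, axes: np.ndarray, phase0: float) -> np.ndarray:
    """Unit step directions precessing on a cone around a per-step axis."""
    dirs = np.empty((n_steps, 3))
    phase = phase0
    for i in range(n_steps):
        a = axes[i]
        # orthonormal frame around the axis
        ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        dirs[i] = np.cos(CONE) * a + np.sin(CONE) * (np.cos(phase) * e1 + np.sin(phase) * e2)
        phase += TWIST
    return dirs


def make_reference_backbone(residue_count: int, seed: int = 0) -> CaTrace:
    """Smooth self-avoiding Cα trace with exact 3.8 Å consecutive distances.

    Ideal-helix segments (random lengths 20-40 residues) whose axes turn by
    a random angle up to ~60° at each junction.  Candidates with any
    nonbonded pair (|i-j| >= 3) closer than 3.5 Å are rejected and redrawn
    from the next sub-seed, so the output is deterministic per seed.
    """
    if residue_count < 10:
        raise ValueError("residue_count must be >= 10")
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        n_steps = residue_count - 1
        # segment axes: start random, rotate at junctions
        axes = np.empty((n_steps, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        i = 0
        while i < n_steps:
            seg = int(rng.integers(20, 41))
            axes[i : i + seg] = axis
            i += seg
            rotvec = rng.normal(size=3)
            rotvec *= rng.uniform(0.2, 1.0) / np.linalg.norm(rotvec)  # <= ~60 deg
            axis = Rotation.from_rotvec(rotvec).apply(axis)
            axis /= np.linalg.norm(axis)
        dirs = _helix_directions(n_steps, axes, phase0=rng.uniform(0, 2 * np.pi))
        coords = np.vstack([np.zeros(3), np.cumsum(STEP * dirs, axis=0)])
        # clash check
        tree = cKDTree(coords)
        ok = True
        for a, b in tree.query_pairs(CLASH_DISTANCE):
            if abs(a - b) >= 3:
                ok = False
                break
        if ok:
            return CaTrace(coords - coords.mean(axis=0), label=f"reference_seed{seed}")
    raise RuntimeError(f"could not generate a clash-free backbone for seed {seed}")


def _class_modes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency sinusoidal displacement fields, one (n_res, 3) per class."""
    n = spec.residue_count
    t = np.arange(n) / (n - 1)
    modes = np.empty((spec.n_classes, n, 3))
    for c in range(spec.n_classes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        freq = c + 1  # distinct wave counts per class
        profile = np.sin(2 * np.pi * freq * t + phase)
        # unit-RMS profile: class_shift_scale is the per-atom RMS amplitude
        # of the field, independent of frequency and phase; full waves keep
        # the deformation from being absorbable by a rigid rotation
        profile = profile / np.sqrt(np.mean(profile**2))
        modes[c] = spec.class_shift_scale * profile[:, None] * direction
    return modes


def make_template_ensemble(
    spec: SyntheticSpec, energy_model=None
) -> tuple[TemplateEnsemble, CaTrace, ClassPartition]:
    """Generate a decoy ensemble with planted classes and a planted reference.

    Returns the ensemble (templates in a common frame, flattened), the
    reference backbone, and the ground-truth class partition.  Energies
    come from ``energy_model`` (default: the surrogate potential); with
    ``spec.class_energy_offset > 0`` a per-class offset
    ``offset * class_index`` is added so the classes are recoverable by
    1-D k-means on energy alone.
    """
    if energy_model is None:
        energy_model = SurrogateEnergy()
    rng = np.random.default_rng(spec.seed)
    reference = make_reference_backbone(spec.residue_count, seed=spec.seed)
    modes = _class_modes(spec, rng)

    traces: list[CaTrace] = []
    truth_labels: list[int] = []
    for c in range(spec.n_classes):
        center = reference.coords + modes[c]
        for t in range(spec.templates_per_class):
            noise = rng.normal(0.0, spec.within_noise, size=center.shape)
            traces.append(CaTrace(center + noise, label=f"class{c}_decoy{t:03d}"))
            truth_labels.append(c)

    energies = np.array([float(energy_model(tr)) for tr in traces])
    if spec.class_energy_offset > 0:
        energies = energies + spec.class_energy_offset * np.array(truth_labels, dtype=float)

    ensemble = TemplateEnsemble.from_traces(traces, energies)
    truth = ClassPartition(
        k=spec.n_classes,
        labels=np.array(truth_labels),
        class_sizes=np.full(spec.n_classes, spec.templates_per_class),
    )
    return ensemble, reference, truth
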