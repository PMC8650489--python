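"""Synthetic task-fMRI cohorts with planted modular structure.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any imaging data:

* a block design (task-first alternation of task and rest blocks, default
  15 blocks of 30 s tapping + 30 s rest at TR = 2.5 s, i.e. 360 volumes);
* a planted community structure — each ROI belongs to one of M modules and
  follows its module's latent signal during task volumes only, plus a
  weaker global latent shared by all modules ("between-module leakage")
  and additive Gaussian observation noise;
* per-group effects expressed as coupling deltas and a list of inactive
  ROIs (downgraded to pure noise), giving group comparisons true positives
  to detect;
* motion traces with Bernoulli-placed spikes above the censoring threshold.

Everything is a deterministic function of the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import ROITimeSeries

__all__ = [
    "TaskDesign",
    "GroupEffect",
    "PlantedStructure",
    "MotionTrace",
    "CohortSpec",
    "SubjectRecord",
    "make_block_design",
    "make_roi_names",
    "simulate_subject",
    "simulate_cohort",
    "make_atlas_fixture",
    "paper_scale_spec",
    "small_spec",
]


@dataclass(frozen=True)
class TaskDesign:
    """Block design: alternating task and rest, task first."""

    n_blocks: int
    task_s: float
    rest_s: float
    tr_s: float
    task_mask: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.task_mask.size

    @property
    def n_task_volumes(self) -> int:
        return int(self.task_mask.sum())


def make_block_design(n_blocks: int, task_s: float, rest_s: float, tr_s: float) -> TaskDesign:
    """Build the boolean task mask of an alternating block design.

    Every block contributes ``task_s / tr_s`` task volumes followed by
    ``rest_s / tr_s`` rest volumes; both durations must divide evenly by
    the TR.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if tr_s <= 0:
        raise ValueError(f"tr_s must be positive, got {tr_s}")
    n_task, r_task = divmod(task_s, tr_s)
    n_rest, r_rest = divmod(rest_s, tr_s)
    if r_task or r_rest:
        raise ValueError(
            f"block durations must be divisible by TR={tr_s}s "
            f"(remainders: task {r_task}s, rest {r_rest}s)")
    block = np.concatenate([
        np.ones(int(round(n_task)), dtype=bool),
        np.zeros(int(round(n_rest)), dtype=bool),
    ])
    mask = np.tile(block, n_blocks)
    return TaskDesign(n_blocks=n_blocks, task_s=task_s, rest_s=rest_s,
                      tr_s=tr_s, task_mask=mask)


@dataclass(frozen=True)
class GroupEffect:
    """Group-specific deviation from the baseline planted structure."""

    within_delta: float = 0.0
    between_delta: float = 0.0
    inactive_rois: tuple[int, ...] = ()  # ROI indices downgraded to pure noise


@dataclass
class PlantedStructure:
    """Baseline community structure shared by all subjects.

    ``within_coupling`` scales each ROI's loading on its module latent,
    ``between_coupling`` its loading on a global latent shared across
    modules; both act during task volumes only.
    """

    affiliation: np.ndarray  # module index per ROI, 1..M
    within_coupling: float = 0.6
    between_coupling: float = 0.1
    noise_sd: float = 1.0
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affiliation = np.asarray(self.affiliation, dtype=np.int64)
        if self.affiliation.min() < 1:
            raise ValueError("module indices must start at 1")
        if not (0.0 <= self.within_coupling < 1.0):
            raise ValueError("within_coupling must lie in [0, 1)")
        if not (0.0 <= self.between_coupling <= self.within_coupling):
            raise ValueError("between_coupling must lie in [0, within_coupling]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_modules(self) -> int:
        return int(self.affiliation.max())

    def couplings_for(self, group: str) -> tuple[float, float, tuple[int, ...]]:
        eff = self.group_effects.get(group, GroupEffect())
        w = float(np.clip(self.within_coupling + eff.within_delta, 0.0, 0.999))
        b = float(np.clip(self.between_coupling + eff.between_delta, 0.0, w))
        return w, b, eff.inactive_rois


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume differential head movement in mm per TR."""

    mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mm", np.asarray(self.mm, dtype=float))
        if np.any(self.mm < 0):
            raise ValueError("motion must be non-negative")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the single source of randomness."""

    n_per_group: dict[str, int]
    n_rois: int
    design: TaskDesign
    structure: PlantedStructure
    motion_spike_rate: float = 0.05
    motion_spike_mm: float = 1.0
    seed: int = 0
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.n_per_group or any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("every group needs >= 1 subject")
        if self.n_rois < 2:
            raise ValueError("need >= 2 ROIs")
        if not (0.0 <= self.motion_spike_rate <= 1.0):
            raise ValueError("motion_spike_rate must lie in [0, 1]")
        if self.structure.affiliation.size != self.n_rois:
            raise ValueError("affiliation length must equal n_rois")
        if self.roi_names is None:
            width = max(3, len(str(self.n_rois)))
            self.roi_names = [f"roi_{i + 1:0{width}d}" for i in range(self.n_rois)]
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    timeseries: ROITimeSeries
    motion: MotionTrace


def simulate_subject(spec: CohortSpec, group: str, subject_seed: int) -> tuple[ROITimeSeries, MotionTrace]:
    """One subject's ROI time series and motion trace.

    Signal model per ROI r with module m(r), during task volumes:
    ``x_r = w * z_{m(r)} + b * g + noise``, where z are independent
    standard-Gaussian module latents, g a global latent, w/b the group's
    within/between couplings.  During rest (and for inactive ROIs
    everywhere) only the noise term remains.  Fully reproducible from
    ``(spec.seed, subject_seed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(subject_seed)]))
    design = spec.design
    n_vol = design.n_volumes
    st = spec.structure
    w, b, inactive = st.couplings_for(group)
    m = st.n_modules

    latents = rng.standard_normal((m, n_vol))
    global_latent = rng.standard_normal(n_vol)
    noise = rng.standard_normal((spec.n_rois, n_vol)) * st.noise_sd
    task = design.task_mask.astype(float)

    signal = (w * latents[st.affiliation - 1] + b * global_latent) * task
    if inactive:
        signal[np.asarray(inactive, dtype=np.int64)] = 0.0
    values = signal + noise

    baseline = rng.uniform(0.0, 0.2, size=n_vol)
    spikes = rng.random(n_vol) < spec.motion_spike_rate
    motion = baseline + spikes * spec.motion_spike_mm

    ts = ROITimeSeries(values=values, roi_names=list(spec.roi_names),
                       tr_s=design.tr_s)
    return ts, MotionTrace(mm=motion)


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """All subjects of a cohort, with per-subject seeds derived from spec.seed.

    Subject k (in group-then-index order) uses subject_seed = k, so the
    cohort is a pure function of the spec.
    """
    records: list[SubjectRecord] = []
    counter = 0
    for group, n in spec.n_per_group.items():
        for i in range(n):
            ts, motion = simulate_subject(spec, group, subject_seed=counter)
            records.append(SubjectRecord(
                subject_id=f"{group}_{i + 1:02d}", group=group,
                timeseries=ts, motion=motion))
            counter += 1
    return records


def make_roi_names(n_cortical: int, n_subcortical: int, n_cerebellar: int) -> list[str]:
    """ROI labels with compartment prefixes (ctx/sub/cbl)."""
    names = [f"ctx_{i + 1:03d}" for i in range(n_cortical)]
    names += [f"sub_{i + 1:03d}" for i in range(n_subcortical)]
    names += [f"cbl_{i + 1:03d}" for i in range(n_cerebellar)]
    return names


def make_atlas_fixture(n_cortical: int, n_subcortical: int, n_cerebellar: int,
                       grid_shape: tuple[int, int, int], seed: int = 0
                       ) -> tuple[np.ndarray, list[str]]:
    """Integer label volume for testing the extraction path.

    Each ROI owns at least two voxels; label 0 is background; voxel
    assignment is a seeded shuffle so ROIs are not spatially trivial.
    Returns the label array and the ROI names (label r -> names[r-1]).
    """
    n_rois = n_cortical + n_subcortical + n_cerebellar
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    n_vox = int(np.prod(grid_shape))
    per_roi = n_vox // n_rois
    if per_roi < 2:
        raise ValueError(
            f"grid {grid_shape} has {n_vox} voxels; cannot give "
            f"{n_rois} ROIs >= 2 voxels each")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_vox)
    labels = np.zeros(n_vox, dtype=np.int32)
    for r in range(n_rois):
        labels[order[r * per_roi:(r + 1) * per_roi]] = r + 1
    return labels.reshape(grid_shape), make_roi_names(
        n_cortical, n_subcortical, n_cerebellar)


def paper_scale_spec(seed: int = 0) -> CohortSpec:
    """Full-scale study preset: 212 ROIs, 360 volumes, 26 + 20 subjects.

    212 ROIs (142 cortical / 36 subcortical / 34 cerebellar) carry a
    planted 3-module structure in contiguous thirds; the patient-analog
    group couples more strongly within modules and recruits fewer ROIs
    (20 inactive), mirroring the qualitative group differences the
    analysis is built to detect.
    """
    design = make_block_design(n_blocks=15, task_s=30, rest_s=30, tr_s=2.5)
    n_rois = 212
    affiliation = 1 + (np.arange(n_rois) * 3) // n_rois
    structure = PlantedStructure(
        affiliation=affiliation,
        within_coupling=0.6,
        between_coupling=0.1,
        noise_sd=1.0,
        group_effects={
            "patient": GroupEffect(within_delta=0.15,
                                   inactive_rois=tuple(range(n_rois - 20, n_rois))),
        },
    )
    return CohortSpec(
        n_per_group={"control": 26, "patient": 20},
        n_rois=n_rois,
        design=design,
        structure=structure,
        seed=seed,
        roi_names=make_roi_names(142, 36, 34),
    )


def small_spec(seed: int = 0, n_rois: int = 60, n_modules: int = 3,
               within: float = 0.9, between: float = 0.0,
               n_per_group: dict[str, int] | None = None) -> CohortSpec:
    """Down-scaled cohort for fast experiments (default 60 ROIs, 3 modules)."""
    design = make_block_design(n_blocks=15, task_s=30, rest_s=30, tr_s=2.5)
    affiliation = 1 + (np.arange(n_rois) * n_modules) // n_rois
    structure = PlantedStructure(
        affiliation=affiliation, within_coupling=within,
        between_coupling=between, noise_sd=1.0)
    return CohortSpec(
        n_per_group=n_per_group or {"A": 1},
        n_rois=n_rois, design=design, structure=structure, seed=seed)
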