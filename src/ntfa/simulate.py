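"""Synthetic fMRI segment simulator for degeneracy scenarios.

Emulates a two-condition experiment (baseline vs experimental) in which
each participant completes 8 trials: 2 baseline and 6 experimental, the
latter split evenly over three trial types A, B and C (20 TRs per trial
by default). Activation patterns are sums of spherical Gaussian "areas"
rendered on a downsampled MNI-proportioned grid, and segments are the
pattern repeated over TRs plus i.i.d. Gaussian noise.

Three scenarios differ only in how templates are shared:

* ``non_degenerate`` — A, B and C share one template (one activation
  pattern for the whole experimental condition),
* ``by_condition`` — A, B and C each have a distinct template shared by
  all participants,
* ``by_condition_and_participant`` — additionally, trial types A and C
  have participant-specific variants (participants past the first share
  the group template's areas except one, which is replaced by a new
  area), while B stays shared.

SNR is defined as sd(rendered signal over in-mask voxels) / sd(noise);
baseline trials carry a zero template, so their noise sd falls back to
the scenario's configured absolute floor (set to the mean experimental
noise sd so every trial is equally noisy). No hemodynamic response
convolution, drift, or nuisance structure is simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .grids import BrainGrid, make_brain_grid

logger = logging.getLogger(__name__)

SCENARIOS = ("non_degenerate", "by_condition", "by_condition_and_participant")
TRIAL_TYPES = ("baseline", "A", "B", "C")
EXPERIMENTAL_TYPES = ("A", "B", "C")

#: default trial plan: 2 baseline + 2 each of A/B/C, 8 trials per participant
DEFAULT_TRIAL_PLAN = (
    (1, "baseline"), (2, "baseline"),
    (3, "A"), (4, "A"), (5, "B"), (6, "B"), (7, "C"), (8, "C"),
)

DEFAULT_REGION_WIDTH_MM = 12.0
#: centers at least this many widths apart keep areas disjoint at half-maximum
REGION_SEPARATION_FACTOR = 4.0
RENDER_CUTOFF = 1e-12


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class ActivationTemplate:
    """A sum of spherical Gaussian areas rendered on a grid.

    ``rendered[v] = sum_r amplitudes[r] * exp(-||coords[v]-centers[r]||^2
    / (2 widths[r]^2))``, with entries below a numeric cutoff zeroed.
    """

    region_centers: np.ndarray  # (R, 3) mm
    region_widths: np.ndarray   # (R,) mm
    amplitudes: np.ndarray      # (R,)
    rendered: np.ndarray = field(repr=False)  # (V,)

    @property
    def n_regions(self) -> int:
        return self.region_centers.shape[0]


def render_template(region_centers, region_widths, amplitudes,
                    grid: BrainGrid) -> ActivationTemplate:
    """Render Gaussian areas onto the grid's in-mask voxels."""
    centers = np.atleast_2d(np.asarray(region_centers, dtype=float))
    widths = np.atleast_1d(np.asarray(region_widths, dtype=float))
    amps = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if centers.shape[0] == 0:
        rendered = np.zeros(grid.n_voxels)
    else:
        d2 = ((grid.coords[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
        bumps = amps[:, None] * np.exp(-d2 / (2.0 * widths[:, None] ** 2))
        rendered = bumps.sum(axis=0)
        rendered[np.abs(rendered) < RENDER_CUTOFF] = 0.0
    return ActivationTemplate(centers, widths, amps, rendered)


def zero_template(grid: BrainGrid) -> ActivationTemplate:
    return render_template(np.empty((0, 3)), np.empty(0), np.empty(0), grid)


def _sample_centers(rng: np.random.Generator, grid: BrainGrid, n: int,
                    min_sep: float, existing=None) -> np.ndarray:
    """Uniform in-mask centers with a minimum pairwise separation."""
    chosen = [] if existing is None else [np.asarray(c) for c in existing]
    n_existing = len(chosen)
    for _ in range(n):
        for attempt in range(1000):
            c = grid.coords[rng.integers(grid.n_voxels)]
            if all(np.linalg.norm(c - o) >= min_sep for o in chosen):
                chosen.append(c)
                break
        else:  # grid too small for the separation constraint; take anything new
            logger.warning("could not honour region separation %.1f mm", min_sep)
            chosen.append(grid.coords[rng.integers(grid.n_voxels)])
    return np.asarray(chosen[n_existing:], dtype=float)


def _sample_template(rng, grid, n_regions, width_mm) -> ActivationTemplate:
    centers = _sample_centers(rng, grid, n_regions, min_sep=REGION_SEPARATION_FACTOR * width_mm)
    widths = np.full(n_regions, width_mm)
    amps = np.ones(n_regions)
    return render_template(centers, widths, amps, grid)


def _participant_variant(rng, grid, group: ActivationTemplate,
                         width_mm) -> ActivationTemplate:
    """Participant-specific variant: drop one group area, add a new one."""
    drop = int(rng.integers(group.n_regions))
    keep = [i for i in range(group.n_regions) if i != drop]
    kept_centers = group.region_centers[keep]
    new = _sample_centers(rng, grid, 1, min_sep=REGION_SEPARATION_FACTOR * width_mm,
                          existing=list(kept_centers))
    centers = np.vstack([kept_centers, new])
    widths = np.concatenate([group.region_widths[keep], [width_mm]])
    amps = np.concatenate([group.amplitudes[keep], [1.0]])
    return render_template(centers, widths, amps, grid)


# ---------------------------------------------------------------------------
# scenario specification


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete data-generating configuration for one simulated study."""

    scenario: str
    n_participants: int
    trial_plan: tuple  # ordered ((trial_id, trial_type), ...)
    templates: dict    # (trial_type, participant_id | None) -> ActivationTemplate
    T: int
    snr: float
    seed: int
    grid: BrainGrid
    noise_floor: float = 0.0

    def template_for(self, trial_type: str, participant_id: int) -> ActivationTemplate:
        t = self.templates.get((trial_type, participant_id))
        return t if t is not None else self.templates[(trial_type, None)]

    def validate(self) -> None:
        """Assert the template-sharing structure implied by the scenario tag."""
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        a = self.templates[("A", None)]
        b = self.templates[("B", None)]
        c = self.templates[("C", None)]
        per_participant = [k for k in self.templates if k[1] is not None]
        if self.scenario == "non_degenerate":
            assert a is b is c, "A/B/C must share one template"
            assert not per_participant
        elif self.scenario == "by_condition":
            assert a is not b and b is not c and a is not c
            assert not per_participant
        else:
            assert a is not b and b is not c and a is not c
            assert all(k[0] in ("A", "C") for k in per_participant), \
                "only A and C may be participant-specific"


def make_scenario(
    scenario: str,
    n_participants: int = 2,
    n_regions_per_template: int = 3,
    T: int = 20,
    snr: float = 8.0,
    seed: int = 0,
    grid: BrainGrid | None = None,
    region_width_mm: float = DEFAULT_REGION_WIDTH_MM,
) -> ScenarioSpec:
    """Draw the templates and trial plan for one degeneracy scenario."""
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if n_participants < 1:
        raise ValidationError("n_participants must be >= 1")
    if T < 1:
        raise ValidationError("T must be >= 1")
    if not snr > 0:
        raise ValidationError("snr must be positive")
    grid = grid if grid is not None else make_brain_grid()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0, 0)))

    templates: dict = {("baseline", None): zero_template(grid)}
    if scenario == "non_degenerate":
        shared = _sample_template(rng, grid, n_regions_per_template, region_width_mm)
        for tt in EXPERIMENTAL_TYPES:
            templates[(tt, None)] = shared
    else:
        for tt in EXPERIMENTAL_TYPES:
            templates[(tt, None)] = _sample_template(
                rng, grid, n_regions_per_template, region_width_mm)
        if scenario == "by_condition_and_participant" and n_participants > 1:
            # participants beyond the first get their own A/C variants;
            # B stays shared across everyone
            for pid in range(2, n_participants + 1):
                for tt in ("A", "C"):
                    templates[(tt, pid)] = _participant_variant(
                        rng, grid, templates[(tt, None)], region_width_mm)

    exp_sds = [templates[(tt, None)].rendered.std() for tt in EXPERIMENTAL_TYPES]
    floor = 0.0 if np.isinf(snr) else float(np.mean(exp_sds) / snr)
    return ScenarioSpec(
        scenario=scenario,
        n_participants=int(n_participants),
        trial_plan=DEFAULT_TRIAL_PLAN,
        templates=templates,
        T=int(T),
        snr=float(snr),
        seed=int(seed),
        grid=grid,
        noise_floor=floor,
    )


# ---------------------------------------------------------------------------
# segments and datasets


@dataclass(frozen=True)
class Segment:
    """One participant-trial combination: T x V data plus labels."""

    participant_id: int
    trial_id: int
    trial_type: str
    data: np.ndarray = field(repr=False)  # (T, V)

    def __post_init__(self):
        if np.isnan(self.data).any():
            raise ValidationError("segment data contains missing values")


@dataclass(frozen=True)
class Dataset:
    """A labelled collection of segments on a common grid."""

    grid: BrainGrid
    segments: tuple

    def __post_init__(self):
        pairs = [(s.participant_id, s.trial_id) for s in self.segments]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (participant_id, trial_id) pair")
        pids = sorted({p for p, _ in pairs})
        tids = sorted({t for _, t in pairs})
        if pids and pids != list(range(1, len(pids) + 1)):
            raise ValidationError("participant IDs must be dense 1..P")
        if tids and tids != list(range(1, len(tids) + 1)):
            raise ValidationError("trial IDs must be dense 1..S")

    @property
    def P(self) -> int:
        return len({s.participant_id for s in self.segments})

    @property
    def S(self) -> int:
        return len({s.trial_id for s in self.segments})

    @property
    def N(self) -> int:
        return len(self.segments)

    @property
    def T(self) -> int:
        return self.segments[0].data.shape[0]

    def mean_image(self) -> np.ndarray:
        """Average brain image across all segments and TRs (length V)."""
        return np.mean([s.data.mean(axis=0) for s in self.segments], axis=0)

    def trial_type_of(self, trial_id: int) -> str:
        for s in self.segments:
            if s.trial_id == trial_id:
                return s.trial_type
        raise KeyError(trial_id)


def _segment_rng(spec: ScenarioSpec, participant_id: int, trial_id: int,
                 seed: int | None) -> np.random.Generator:
    # one child stream per segment, keyed by (participant_id, trial_id)
    entropy = spec.seed if seed is None else seed
    return np.random.default_rng(
        np.random.SeedSequence((entropy, participant_id, trial_id)))


def sample_segment(spec: ScenarioSpec, participant_id: int, trial_id: int,
                   seed: int | None = None) -> Segment:
    """Draw one segment: the rendered template over T TRs plus Gaussian noise.

    Noise sd is sd(template)/snr; a zero-signal template (the baseline)
    falls back to ``spec.noise_floor``.
    """
    plan = dict(spec.trial_plan)
    if trial_id not in plan or not (1 <= participant_id <= spec.n_participants):
        raise ValidationError(
            f"({participant_id}, {trial_id}) is not in the scenario plan")
    trial_type = plan[trial_id]
    template = spec.template_for(trial_type, participant_id)
    sd_signal = float(template.rendered.std())
    if sd_signal > 0 and not np.isinf(spec.snr):
        sd_noise = sd_signal / spec.snr
    else:
        sd_noise = 0.0 if np.isinf(spec.snr) else spec.noise_floor
        if sd_signal == 0 and not np.isinf(spec.snr):
            logger.info("zero-signal template for trial %d; noise sd floored "
                        "at %.4g", trial_id, sd_noise)
    rng = _segment_rng(spec, participant_id, trial_id, seed)
    data = np.broadcast_to(template.rendered, (spec.T, template.rendered.size)).copy()
    if sd_noise > 0:
        data += rng.normal(0.0, sd_noise, size=data.shape)
    return Segment(participant_id=int(participant_id), trial_id=int(trial_id),
                   trial_type=trial_type, data=data)


def simulate_dataset(spec: ScenarioSpec) -> Dataset:
    """One segment per (participant, trial) in the plan; seeded and deterministic."""
    segments = [
        sample_segment(spec, pid, tid)
        for pid in range(1, spec.n_participants + 1)
        for tid, _ in spec.trial_plan
    ]
    return Dataset(grid=spec.grid, segments=tuple(segments))


# ---------------------------------------------------------------------------
# on-disk format: one 4-D NIfTI per segment + events TSV + JSON manifest

EVENTS_COLUMNS = ["segment_file", "participant_id", "trial_id", "trial_type", "T"]


def write_dataset(ds: Dataset, dir_path, scenario: str | None = None,
                  seed: int | None = None) -> dict:
    """Write the dataset; returns the manifest dict (also saved as JSON)."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in ds.segments:
        fname = f"seg_p{seg.participant_id:03d}_t{seg.trial_id:03d}.nii.gz"
        vol = ds.grid.embed(seg.data.astype(np.float32))  # (T, X, Y, Z)
        img = nib.Nifti1Image(np.moveaxis(vol, 0, -1), ds.grid.affine)
        nib.save(img, out / fname)
        rows.append([fname, seg.participant_id, seg.trial_id, seg.trial_type,
                     seg.data.shape[0]])
    events = pd.DataFrame(rows, columns=EVENTS_COLUMNS)
    events.to_csv(out / "events.tsv", sep="\t", index=False)
    nib.save(nib.Nifti1Image(ds.grid.mask.astype(np.uint8), ds.grid.affine),
             out / "mask.nii.gz")
    manifest = {
        "grid_shape": list(ds.grid.shape),
        "voxel_size_mm": ds.grid.voxel_size_mm,
        "scenario": scenario,
        "seed": seed,
        "n_segments": ds.N,
        "n_participants": ds.P,
        "n_trials": ds.S,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(dir_path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    src = Path(dir_path)
    events_path = src / "events.tsv"
    if not events_path.exists():
        raise FormatError(f"missing events table {events_path}")
    manifest = json.loads((src / "manifest.json").read_text())
    mask_img = nib.load(src / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    vox = float(manifest["voxel_size_mm"])
    from .grids import _voxel_centers
    coords = _voxel_centers(mask.shape, vox)[mask.reshape(-1)]
    grid = BrainGrid(shape=tuple(mask.shape), voxel_size_mm=vox,
                     mask=mask, coords=coords)

    events = pd.read_csv(events_path, sep="\t")
    missing = set(EVENTS_COLUMNS) - set(events.columns)
    if missing:
        raise FormatError(f"events table missing columns {sorted(missing)}")
    if events.duplicated(["participant_id", "trial_id"]).any():
        raise FormatError("events table has a duplicated (participant, trial) pair")

    segments = []
    for _, row in events.iterrows():
        img = nib.load(src / row["segment_file"])
        arr = np.asarray(img.dataobj, dtype=np.float32)
        if arr.ndim != 4 or arr.shape[:3] != grid.shape:
            raise FormatError(
                f"{row['segment_file']}: shape {arr.shape} does not match "
                f"grid {grid.shape}")
        data = grid.extract(np.moveaxis(arr, -1, 0))
        if data.shape[0] != int(row["T"]):
            raise FormatError(f"{row['segment_file']}: T mismatch with events")
        segments.append(Segment(
            participant_id=int(row["participant_id"]),
            trial_id=int(row["trial_id"]),
            trial_type=str(row["trial_type"]),
            data=data.astype(np.float64),
        ))
    return Dataset(grid=grid, segments=tuple(segments))
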