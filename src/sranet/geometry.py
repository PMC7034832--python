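"""Superposition-based RMSD/RMSF, replica QC, tail slicing and distance KDEs.

Alignment conventions:

* RMSD series fit every frame to a reference (the run's initial structure or
  an external crystal structure) on a fit selection — typically the protein
  Cα atoms without the terminal regions — then measure RMSD over a possibly
  different calc selection without refitting.  This is how DNA divergence is
  scored while the protein stays superposed.
* RMSF uses a two-pass protocol: frames are prefit to the first frame, the
  mean structure is computed, frames are refit to that mean, and per-atom
  fluctuations are taken about the mean positions.  Per-residue values are
  unweighted means over the residue's heavy atoms.
* Replica QC excludes a replica when its tail-window RMSD (protein fit, DNA
  calc, crystal reference) exceeds a threshold, 4 Å by default; exclusions
  are reported, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import scipy.stats

from .model_io import Selection, Trajectory

__all__ = [
    "QC_RMSD_THRESHOLD",
    "RMSDSeries",
    "RMSFProfile",
    "DistanceDistribution",
    "ReplicaQCResult",
    "FittingError",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf_profile",
    "qc_replicas",
    "slice_tail",
    "ring_distance_series",
    "gaussian_kde",
]

QC_RMSD_THRESHOLD = 4.0   # Å


class FittingError(ValueError):
    """Superposition impossible (too few atoms or degenerate geometry)."""


class DegenerateInputError(ValueError):
    """Input carries no variance (e.g. constant KDE samples)."""


# ---------------------------------------------------------------------------
# superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_set: Selection | np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the fit
    atoms.  The rotation is proper (determinant +1, Kabsch correction).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _indices(fit_set, len(mobile))
    x = mobile[idx]
    y = reference[idx]
    if len(x) < 3:
        raise FittingError(f"need >= 3 fit atoms, got {len(x)}")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise FittingError("fit atoms are collinear or coincident")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def _indices(sel, n: int) -> np.ndarray:
    if sel is None:
        return np.arange(n)
    if isinstance(sel, Selection):
        return sel.resolved
    return np.asarray(sel, dtype=int)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) after fitting each frame on the fit selection."""

    values: np.ndarray
    fit_selection: Selection | None
    calc_selection: Selection | None
    reference_label: str = "first_frame"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")


def rmsd_series(trajectory: Trajectory, fit_set: Selection | None,
                calc_set: Selection | None,
                reference: np.ndarray | None = None,
                reference_label: str = "first_frame") -> RMSDSeries:
    """RMSD per frame: fit on ``fit_set`` to the reference, measure over
    ``calc_set`` without refitting.  ``reference=None`` uses the first frame."""
    if reference is None:
        reference = trajectory.coords[0]
    reference = np.asarray(reference, dtype=float)
    calc_idx = _indices(calc_set, trajectory.topology.n_atoms)
    values = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.coords):
        rot, trans, _ = superpose(frame, reference, fit_set)
        fitted = apply_transform(frame, rot, trans)
        values[f] = _rmsd(fitted[calc_idx], reference[calc_idx])
    return RMSDSeries(values=values, fit_selection=fit_set,
                      calc_selection=calc_set, reference_label=reference_label)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) over heavy atoms, plus the per-atom values."""

    residue_labels: list[str]
    residue_values: np.ndarray
    atom_indices: np.ndarray
    atom_values: np.ndarray

    def as_table(self) -> str:
        lines = ["residue\trmsf"]
        for label, value in zip(self.residue_labels, self.residue_values):
            lines.append(f"{label}\t{value:.6f}")
        return "\n".join(lines) + "\n"


def rmsf_profile(trajectory: Trajectory, fit_set: Selection | None,
                 calc_set: Selection | None = None) -> RMSFProfile:
    """Root-mean-square fluctuation per heavy atom, averaged per residue.

    Two-pass protocol: (1) prefit all frames to the first frame on
    ``fit_set``; (2) compute the mean structure; (3) refit all frames to the
    mean; (4) per-atom RMSF about the mean position; (5) unweighted mean over
    each residue's heavy atoms in ``calc_set``.  Residues contributing no
    heavy atoms are omitted with a warning.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = trajectory.topology
    n = top.n_atoms
    calc_idx = set(_indices(calc_set, n).tolist())
    heavy = {i for i in calc_idx if top.atoms[i].element.upper() != "H"}

    prefit = np.empty_like(trajectory.coords)
    first = trajectory.coords[0]
    for f, frame in enumerate(trajectory.coords):
        rot, trans, _ = superpose(frame, first, fit_set)
        prefit[f] = apply_transform(frame, rot, trans)
    mean_structure = prefit.mean(axis=0)

    refit = np.empty_like(prefit)
    for f, frame in enumerate(prefit):
        rot, trans, _ = superpose(frame, mean_structure, fit_set)
        refit[f] = apply_transform(frame, rot, trans)
    mean_final = refit.mean(axis=0)
    sq_dev = np.sum((refit - mean_final[None]) ** 2, axis=2)   # (frames, atoms)
    atom_rmsf = np.sqrt(sq_dev.mean(axis=0))

    labels: list[str] = []
    values: list[float] = []
    for res in top.residues:
        atoms = [i for i in res.atom_indices if i in heavy]
        if not atoms:
            warnings.warn(
                f"residue {res.name}{res.index} has no heavy atoms in the "
                "calc selection; omitted from RMSF profile")
            continue
        labels.append(f"{res.name}{res.index}")
        values.append(float(atom_rmsf[atoms].mean()))
    heavy_sorted = np.array(sorted(heavy), dtype=int)
    return RMSFProfile(residue_labels=labels,
                       residue_values=np.array(values),
                       atom_indices=heavy_sorted,
                       atom_values=atom_rmsf[heavy_sorted])


# ---------------------------------------------------------------------------
# replica QC and tail slicing
# ---------------------------------------------------------------------------

@dataclass
class ReplicaQCResult:
    replica_id: str
    passed: bool
    max_tail_rmsd: float
    mean_tail_rmsd: float
    threshold: float
    n_tail_frames: int

    @property
    def status(self) -> str:
        return "pass" if self.passed else "excluded"


def qc_replicas(replicas: list[Trajectory], fit_set: Selection | None,
                calc_set: Selection | None, threshold: float = QC_RMSD_THRESHOLD,
                tail: int | None = None,
                reference: np.ndarray | None = None) -> list[ReplicaQCResult]:
    """Flag replicas whose tail-window RMSD exceeds ``threshold``.

    Per replica, the RMSD series is computed with the standard convention —
    protein fit on ``fit_set``, deviation over ``calc_set`` (typically DNA),
    reference defaulting to the replica's first frame (pass the crystal
    structure for an external reference).  Only the last ``tail`` frames are
    scored; a replica is excluded iff its maximum tail RMSD exceeds the
    threshold.  Decisions are independent of replica order.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    results = []
    for rep in replicas:
        series = rmsd_series(rep, fit_set, calc_set, reference=reference)
        n_tail = len(series.values)
        if tail is not None:
            if tail > n_tail:
                warnings.warn(
                    f"tail window {tail} exceeds trajectory length {n_tail}; "
                    "clipped")
            n_tail = min(tail, n_tail)
        window = series.values[-n_tail:]
        max_rmsd = float(window.max())
        results.append(ReplicaQCResult(
            replica_id=rep.replica_id,
            passed=max_rmsd <= threshold,
            max_tail_rmsd=max_rmsd,
            mean_tail_rmsd=float(window.mean()),
            threshold=threshold,
            n_tail_frames=int(n_tail)))
    return results


def slice_tail(trajectory: Trajectory, last_n_frames: int | None = None,
               last_ns: float | None = None) -> Trajectory:
    """Keep only the trailing window of a trajectory (metadata preserved).

    Exactly one of ``last_n_frames`` / ``last_ns`` must be given; a time
    window resolves to the nearest frame count assuming the uniform spacing
    of ``frame_times``.  Requests longer than the trajectory clip with a
    warning.
    """
    if (last_n_frames is None) == (last_ns is None):
        raise ValueError("give exactly one of last_n_frames / last_ns")
    n = trajectory.n_frames
    if last_ns is not None:
        if last_ns <= 0:
            raise ValueError("last_ns must be positive")
        if n > 1:
            dt_ps = float(trajectory.frame_times[1] - trajectory.frame_times[0])
            keep = int(round(last_ns * 1000.0 / dt_ps))
        else:
            keep = 1
        keep = max(keep, 1)
    else:
        if last_n_frames <= 0:
            raise ValueError("last_n_frames must be positive")
        keep = last_n_frames
    if keep > n:
        warnings.warn(f"requested tail of {keep} frames exceeds trajectory "
                      f"length {n}; keeping all frames")
        keep = n
    return Trajectory(topology=trajectory.topology,
                      coords=trajectory.coords[n - keep:],
                      frame_times=trajectory.frame_times[n - keep:],
                      replica_id=trajectory.replica_id,
                      system_label=trajectory.system_label)


# ---------------------------------------------------------------------------
# distances and KDE
# ---------------------------------------------------------------------------

class KernelDensity:
    """Gaussian kernel density estimate with an absolute bandwidth in Å.

    Thin wrapper over scipy's Gaussian KDE translating a fixed bandwidth in
    data units into scipy's covariance-factor convention; ``bandwidth`` is
    the kernel standard deviation actually used.
    """

    def __init__(self, samples: np.ndarray, bandwidth: str | float = "scott"):
        samples = np.asarray(samples, dtype=float).ravel()
        if len(samples) < 2:
            raise DegenerateInputError("KDE needs at least 2 samples")
        sd = samples.std(ddof=1)
        if sd == 0 or not np.isfinite(sd) or np.ptp(samples) < 1e-12:
            raise DegenerateInputError("KDE input has zero variance")
        if bandwidth == "scott":
            self._kde = scipy.stats.gaussian_kde(samples, bw_method="scott")
        elif isinstance(bandwidth, (int, float)):
            if bandwidth <= 0:
                raise ValueError("fixed bandwidth must be positive")
            self._kde = scipy.stats.gaussian_kde(
                samples, bw_method=float(bandwidth) / sd)
        else:
            raise ValueError(f"unknown bandwidth {bandwidth!r}")
        self.samples = samples
        self.bandwidth = float(np.sqrt(self._kde.covariance[0, 0]))

    def __call__(self, x) -> np.ndarray:
        return self._kde(np.atleast_1d(np.asarray(x, dtype=float)))

    def integral(self, n_points: int = 4096) -> float:
        """Numerically integrate over ±6 bandwidths beyond the sample range."""
        lo = self.samples.min() - 6 * self.bandwidth
        hi = self.samples.max() + 6 * self.bandwidth
        grid = np.linspace(lo, hi, n_points)
        return float(np.trapezoid(self(grid), grid))


def gaussian_kde(samples: np.ndarray,
                 bandwidth: str | float = "scott") -> KernelDensity:
    """Gaussian KDE of a sample; ``bandwidth`` is Scott's rule or a fixed Å
    value.  The density is non-negative and integrates to 1 (tolerance 1e-3
    over ±6 bandwidths beyond the sample range)."""
    return KernelDensity(samples, bandwidth)


@dataclass
class DistanceDistribution:
    """Per-frame distances (Å) with an attached Gaussian KDE."""

    samples: np.ndarray
    kde: KernelDensity | None
    bandwidth: float | None

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if len(self.samples) > 1 else 0.0


def ring_distance_series(trajectory: Trajectory, ring_a: Selection,
                         ring_b: Selection,
                         bandwidth: str | float = "scott"
                         ) -> DistanceDistribution:
    """Distance between the geometric centres of two rings, per frame.

    Centroids are unweighted means of each ring selection (>= 3 atoms each);
    a Gaussian KDE of the distance samples is attached when the distances
    are not all identical.
    """
    if len(ring_a) < 3 or len(ring_b) < 3:
        raise ValueError("each ring selection needs at least 3 atoms")
    ca = trajectory.coords[:, ring_a.resolved].mean(axis=1)
    cb = trajectory.coords[:, ring_b.resolved].mean(axis=1)
    samples = np.linalg.norm(ca - cb, axis=1)
    try:
        kde = gaussian_kde(samples, bandwidth)
        bw = kde.bandwidth
    except DegenerateInputError:
        kde, bw = None, None
    return DistanceDistribution(samples=samples, kde=kde, bandwidth=bw)
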