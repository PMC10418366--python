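"""Synthetic chi1 trajectory generator: von Mises wells + Markov switching.

Emulates the statistical structure of per-residue chi1 time series from MD
of a protein at two pH conditions, so the whole analysis pipeline is
testable without trajectories.  Each rotamer well is a von Mises emission
(the circular analog of a Gaussian) with concentration kappa ~ 1/sigma_rad^2
derived from the stated angular spread; a frame-to-frame Markov chain
switches between wells.  A pH 7-like residue sits in a single stable well
(mean 190 deg, spread ~9 deg); a pH 2-like responsive residue gains a second
well near 285 deg (spread ~12 deg) with stochastic switching.  Defaults
emulate a 100-ns trajectory saved every 0.1 ns in three replicates per
condition; the hidden state path is always retained so classification and
occupancy can be checked against generator truth.

No force-field physics, solvent or correlated multi-residue motion is
emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .angle_io import DihedralSeries, write_chi_xvg

__all__ = [
    "WellSpec",
    "RegimeSpec",
    "SyntheticDataset",
    "IN_SITE_WELL",
    "OUT_OF_SITE_WELL",
    "single_well_regime",
    "two_well_regime",
    "sample_regime",
    "make_study_set",
    "write_dataset",
]

PH7_LIKE = "pH7"
PH2_LIKE = "pH2"


class RegimeError(ValueError):
    """Invalid generative specification."""


@dataclass(frozen=True)
class WellSpec:
    """A rotamer well: circular mean and spread in degrees."""

    mu: float
    sigma: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 < self.sigma < 60.0:
            raise RegimeError(f"sigma {self.sigma} outside (0, 60) degrees")

    @property
    def kappa(self) -> float:
        """von Mises concentration, kappa ~ 1/sigma_rad^2."""
        return 1.0 / np.deg2rad(self.sigma) ** 2


#: The stable in-site well of the catalytic histidine (chi1 = 190 +/- 9 deg)
IN_SITE_WELL = WellSpec(mu=190.0, sigma=9.0, label="native")
#: The acidic-pH out-of-site well (chi1 = 285 +/- 12 deg)
OUT_OF_SITE_WELL = WellSpec(mu=285.0, sigma=12.0, label="out_of_site")


@dataclass(frozen=True)
class RegimeSpec:
    """Generative spec: wells, per-frame switching matrix, length, seed."""

    wells: tuple[WellSpec, ...]
    transition_matrix: np.ndarray
    n_frames: int = 1000
    frame_dt: float = 0.1
    seed: int = 0
    initial_state: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.wells)
        if T.shape != (k, k):
            raise RegimeError(f"transition matrix must be {k}x{k}")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0):
            raise RegimeError("transition matrix rows must be stochastic")
        if self.n_frames < 1:
            raise RegimeError("n_frames must be >= 1")
        if not 0 <= self.initial_state < k:
            raise RegimeError("initial_state out of range")
        object.__setattr__(self, "transition_matrix", T)
        object.__setattr__(self, "wells", tuple(self.wells))

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the switching chain (left eigenvector)."""
        T = self.transition_matrix
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def single_well_regime(
    well: WellSpec = IN_SITE_WELL,
    n_frames: int = 1000,
    frame_dt: float = 0.1,
    seed: int = 0,
) -> RegimeSpec:
    return RegimeSpec(
        wells=(well,),
        transition_matrix=np.array([[1.0]]),
        n_frames=n_frames,
        frame_dt=frame_dt,
        seed=seed,
    )


def two_well_regime(
    p_exit: float = 0.05,
    p_return: float = 0.02,
    wells: tuple[WellSpec, WellSpec] = (IN_SITE_WELL, OUT_OF_SITE_WELL),
    n_frames: int = 1000,
    frame_dt: float = 0.1,
    seed: int = 0,
) -> RegimeSpec:
    """Two-well switching regime.

    Default per-frame rates give stationary out-of-site occupancy
    ``p_exit / (p_exit + p_return)`` ~ 0.71 — an acidified residue that has
    mostly left its native well but still revisits it, as the expected S_NO
    against a stable-well condition tracks the realized out-of-site
    occupancy — with a handful of sustained excursions per 1000-frame
    replicate.
    """
    T = np.array([[1.0 - p_exit, p_exit], [p_return, 1.0 - p_return]])
    return RegimeSpec(
        wells=wells, transition_matrix=T, n_frames=n_frames,
        frame_dt=frame_dt, seed=seed,
    )


def sample_regime(
    spec: RegimeSpec,
    residue_id: int = 275,
    residue_name: str = "HIS",
) -> tuple[DihedralSeries, np.ndarray]:
    """Draw one trajectory: hidden Markov states and von Mises angles.

    Returns the series (angles on the signed [-180, 180) convention, as the
    GROMACS chi utility writes them) and the hidden state index per frame.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.wells)
    states = np.empty(spec.n_frames, dtype=np.int64)
    states[0] = spec.initial_state
    if k == 1:
        states[:] = spec.initial_state
    else:
        T = spec.transition_matrix
        # inverse-CDF stepping keeps the draw count per frame fixed
        cum = np.cumsum(T, axis=1)
        u = rng.random(spec.n_frames - 1)
        for i in range(1, spec.n_frames):
            states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    mus = np.deg2rad(np.array([w.mu for w in spec.wells]))
    kappas = np.array([w.kappa for w in spec.wells])
    angles = np.rad2deg(rng.vonmises(mus[states], kappas[states]))
    # rng.vonmises returns radians in [-pi, pi) about 0; after the mean shift
    # values can exceed that range, so reduce to the signed convention
    angles = np.mod(angles + 180.0, 360.0) - 180.0
    times = spec.frame_dt * np.arange(spec.n_frames)
    times = times + spec.frame_dt  # first saved frame at one interval
    series = DihedralSeries(
        residue_id=residue_id,
        residue_name=residue_name,
        times=times,
        angles=angles,
        dialect="signed",
    )
    return series, states


@dataclass(frozen=True)
class SyntheticDataset:
    """Series plus generator truth for a replicated two-condition study."""

    series: dict[tuple[int, str, int], DihedralSeries]
    hidden_states: dict[tuple[int, str, int], np.ndarray] = field(repr=False)
    responsive_ids: tuple[int, ...] = ()
    conditions: tuple[str, str] = (PH7_LIKE, PH2_LIKE)
    n_replicates: int = 3
    base_seed: int = 0

    def residues(self) -> list[int]:
        return sorted({key[0] for key in self.series})

    def by_condition(self, condition: str) -> dict[int, list[DihedralSeries]]:
        """Replicate lists per residue for one condition, replicate-ordered."""
        out: dict[int, list[DihedralSeries]] = {}
        for rid in self.residues():
            out[rid] = [
                self.series[(rid, condition, rep)]
                for rep in range(1, self.n_replicates + 1)
            ]
        return out


def _derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic per-trajectory seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_study_set(
    n_residues: int = 20,
    responsive_ids: Sequence[int] = (275,),
    pH7_template: RegimeSpec | None = None,
    pH2_template: RegimeSpec | None = None,
    n_replicates: int = 3,
    base_seed: int = 0,
    first_residue: int = 270,
) -> SyntheticDataset:
    """Replicated two-condition study set with known responsive residues.

    Non-responsive residues follow the single-well template in both
    conditions (with independent replicate seeds, so their paired S_NO
    reflects pure sampling noise); responsive residues follow the single
    well at the pH 7-like condition and the two-well switching regime at
    the pH 2-like condition.  Residue ids default to a contiguous block
    containing the catalytic histidine position 275.
    """
    if pH7_template is None:
        pH7_template = single_well_regime()
    if pH2_template is None:
        pH2_template = two_well_regime(
            n_frames=pH7_template.n_frames, frame_dt=pH7_template.frame_dt
        )
    residue_ids = [first_residue + i for i in range(n_residues)]
    responsive = set(responsive_ids)
    if not responsive <= set(residue_ids):
        raise RegimeError(
            f"responsive ids {sorted(responsive - set(residue_ids))} not in "
            f"the residue block {residue_ids[0]}..{residue_ids[-1]}"
        )
    series: dict[tuple[int, str, int], DihedralSeries] = {}
    hidden: dict[tuple[int, str, int], np.ndarray] = {}
    for ci, condition in enumerate((PH7_LIKE, PH2_LIKE)):
        for rid in residue_ids:
            template = (
                pH2_template
                if (condition == PH2_LIKE and rid in responsive)
                else pH7_template
            )
            for rep in range(1, n_replicates + 1):
                seed = _derive_seed(base_seed, rid, ci, rep)
                spec = replace(template, seed=seed)
                name = "HIS" if rid == 275 else "XAA"
                s, states = sample_regime(spec, residue_id=rid, residue_name=name)
                series[(rid, condition, rep)] = s
                hidden[(rid, condition, rep)] = states
    return SyntheticDataset(
        series=series,
        hidden_states=hidden,
        responsive_ids=tuple(sorted(responsive)),
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write a dataset as xvg files plus a JSON truth/layout manifest.

    Layout: ``<outdir>/<condition>/rep<k>/chi1XXXnnn.xvg`` and a
    ``manifest.json`` mapping conditions to per-residue replicate file lists
    (the layout the pipeline reader consumes) with the generator truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "base_seed": dataset.base_seed,
        "responsive_ids": list(dataset.responsive_ids),
        "n_replicates": dataset.n_replicates,
        "conditions": {},
        "truth": {},
    }
    for (rid, condition, rep), s in sorted(dataset.series.items()):
        rep_dir = outdir / condition / f"rep{rep}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        fname = f"chi1{s.residue_name}{rid}.xvg"
        write_chi_xvg(s, rep_dir / fname)
        rel = str(Path(condition) / f"rep{rep}" / fname)
        manifest["conditions"].setdefault(condition, {}).setdefault(
            str(rid), []
        ).append(rel)
        manifest["truth"].setdefault(f"{rid}|{condition}|{rep}", "".join(
            map(str, dataset.hidden_states[(rid, condition, rep)])
        ))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir / "manifest.json"
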