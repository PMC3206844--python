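"""Monte-Carlo rigid-body refinement of oligomers against scattering data.

Starting from an assembly of rigid components, each step applies a random
rotation (uniform axis, angle uniform in [0, max_rotation]) about one
randomly chosen movable component's centroid plus a random translation
(each coordinate uniform in [-max_translation, +max_translation]).  A
proposal is rejected outright if any inter-component centre pair comes
closer than the clash threshold; otherwise the assembly's Debye profile is
fitted to the experiment (scale refit every step, background optional) and
the move is accepted greedily (delta chi <= 0) or, with temperature > 0,
by the Metropolis rule exp(-delta chi / T).  The first component stays
fixed by default: chi is invariant to a global rigid motion, so pinning
one component removes that degeneracy.

The chi landscape is evaluated with a decomposition that makes the loop
cheap: intra-component Debye terms are invariant under rigid moves and are
computed once; only the moved component's cross terms are rebuilt each
step, via a fixed-width pair-distance histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .scatter import ScatteringCurve, debye_intensity
from .structures import (
    DEFAULT_CLASH_THRESHOLD,
    RigidBodyAssembly,
    RigidTransform,
    StructureError,
)

__all__ = [
    "MCConfig",
    "TraceStep",
    "RefinementResult",
    "RigidBodyModel",
    "propose_move",
    "mc_refine",
    "interface_pairs",
    "ContactPair",
]

#: Histogram bin width (A) for the cross-term Debye evaluation in the loop.
#: Much narrower than the general evaluator's bins because the loop uses
#: fixed bin centres (no per-bin moment corrections) for speed, and the
#: late, fine phase of a greedy descent must resolve intensity differences
#: well below the evaluation error of coarser bins.
CROSS_BIN_WIDTH = 0.005


@dataclass(frozen=True)
class MCConfig:
    """Parameters of the Monte-Carlo refinement.

    ``temperature`` is in chi units; 0 means greedy downhill.  ``anneal``
    multiplies the temperature each step (geometric annealing; 1 = fixed).
    ``moved_components`` defaults to every component except the first,
    which stays fixed to remove the global-pose degeneracy.
    """

    n_steps: int = 3000
    max_rotation: float = 5.0  # degrees per move
    max_translation: float = 0.12  # A per move
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD
    temperature: float = 0.0
    anneal: float = 1.0
    step_decay: float = 0.998
    multiscale: bool = False
    min_scale: float = 0.1
    orbit_fraction: float = 0.0
    restart_interval: int = 1000
    seed: int = 0
    moved_components: tuple[str, ...] | None = None
    fit_background: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.max_rotation < 0 or self.max_translation < 0:
            raise ValueError("step sizes must be >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not 0 < self.anneal <= 1.0:
            raise ValueError("anneal must be in (0, 1]")
        if not 0 < self.step_decay <= 1.0:
            raise ValueError("step_decay must be in (0, 1]")
        if not 0 < self.min_scale <= 1.0:
            raise ValueError("min_scale must be in (0, 1]")
        if not 0 <= self.orbit_fraction <= 1.0:
            raise ValueError("orbit_fraction must be in [0, 1]")
        if self.restart_interval < 0:
            raise ValueError("restart_interval must be >= 0")

    def step_sizes(self, step: int, rng: np.random.Generator) -> tuple[float, float]:
        """Move amplitudes for one step.

        With ``multiscale`` (the default) a per-step factor drawn
        log-uniformly in [min_scale, 1] multiplies both maxima, so coarse
        exploratory moves and the fine moves needed to follow narrow,
        weakly-constrained directions of the chi landscape are both always
        on offer.  ``step_decay`` < 1 adds a geometric shrink on top.
        """
        f = max(self.step_decay ** step, self.min_scale)
        if self.multiscale:
            f *= 10.0 ** rng.uniform(math.log10(self.min_scale), 0.0)
        return self.max_rotation * f, self.max_translation * f


class TraceStep(NamedTuple):
    step: int
    proposed_chi: float  # NaN when the proposal clashed
    accepted: bool
    clash: bool


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of a refinement run.

    ``best_assembly``/``best_chi`` track the best state ever accepted
    (including the start); the trace has one entry per step.
    """

    best_assembly: RigidBodyAssembly
    best_chi: float
    start_chi: float
    trace: tuple[TraceStep, ...]
    n_accepted: int
    n_clashed: int
    config: MCConfig

    def summary(self) -> str:
        n = len(self.trace)
        acc = f"{self.n_accepted}/{n}" if n else "0/0"
        return (
            f"MC rigid-body refinement: chi {self.start_chi:.4g} -> {self.best_chi:.4g}\n"
            f"  steps = {n}, accepted = {acc}, clash-rejected = {self.n_clashed}\n"
            f"  seed = {self.config.seed}, T = {self.config.temperature:g}, "
            f"moves <= {self.config.max_rotation:g} deg / "
            f"{self.config.max_translation:g} A"
        )


def _draw_move(movable: Sequence[str], rng: np.random.Generator,
               max_rotation: float, max_translation: float):
    """One random move: (component id, rotation matrix, translation)."""
    cid = movable[int(rng.integers(len(movable)))]
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    angle = rng.uniform(0.0, math.radians(max_rotation))
    rot = Rotation.from_rotvec(axis * angle).as_matrix()
    trans = rng.uniform(-max_translation, max_translation, size=3) \
        if max_translation > 0 else np.zeros(3)
    return cid, rot, trans


def propose_move(a: RigidBodyAssembly, cfg: MCConfig,
                 rng: np.random.Generator) -> RigidBodyAssembly:
    """One random rigid move applied to one movable component.

    The chosen component's transform is composed with a random rotation
    about its current centroid and a random translation; every other
    component is untouched.
    """
    movable = list(cfg.moved_components) if cfg.moved_components is not None \
        else a.component_ids[1:]
    if not movable:
        raise StructureError("no movable components")
    for cid in movable:
        if cid not in a.components:
            raise StructureError(f"movable component {cid!r} not in assembly")
    cid, rot, trans = _draw_move(movable, rng, cfg.max_rotation, cfg.max_translation)
    return a.replace_transform(cid, a.transforms[cid].compose_about(rot, trans))


class RigidBodyModel:
    """Rigid-body model of an oligomer, fitted to a scattering curve by
    Monte-Carlo refinement.

    Construct from a :class:`RigidBodyAssembly` (>= 2 components) and an
    experimental curve; ``fit`` runs the seeded MC loop and returns a
    :class:`RefinementResult`.
    """

    def __init__(self, assembly: RigidBodyAssembly, experiment: ScatteringCurve) -> None:
        if len(assembly.component_ids) < 2:
            raise StructureError("rigid-body refinement needs >= 2 components")
        if np.any(experiment.sigma <= 0):
            raise ValueError("experiment sigma must be positive")
        self.assembly = assembly
        self.experiment = experiment

    # -- chi evaluation machinery ------------------------------------------

    def _setup(self, cfg: MCConfig):
        a, q = self.assembly, self.experiment.q
        ids = a.component_ids
        state = {
            "coords": {cid: a.transformed_coords(cid) for cid in ids},
            "transforms": dict(a.transforms),
        }
        weights = {cid: a.components[cid].weights for cid in ids}
        intra = sum(debye_intensity(state["coords"][cid], weights[cid], q)
                    for cid in ids)
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        # unit-weight bead pairs need no weight vector (fast bincount path)
        wprod = {}
        for p in pairs:
            wa, wb = weights[p[0]], weights[p[1]]
            if np.all(wa == 1.0) and np.all(wb == 1.0):
                wprod[p] = None
            else:
                wprod[p] = np.outer(wa, wb).ravel()
        # fixed-width histogram bins; headroom for drift during the walk
        d0max = max(cdist(state["coords"][p[0]], state["coords"][p[1]]).max()
                    for p in pairs)
        r_max = d0max * 1.6 + 40.0
        n_bins = int(np.ceil(r_max / CROSS_BIN_WIDTH))
        centers = (np.arange(n_bins) + 0.5) * CROSS_BIN_WIDTH
        sinc = np.sinc(np.outer(q, centers) / np.pi)
        return state, weights, intra, pairs, wprod, (n_bins, n_bins * CROSS_BIN_WIDTH, sinc)

    def _pair_term(self, ca, cb, wp, bins):
        n_bins, r_max, sinc = bins
        d = cdist(ca, cb).ravel()
        idx = np.minimum((d * (n_bins / r_max)).astype(np.intp), n_bins - 1)
        h = np.bincount(idx, weights=wp, minlength=n_bins)
        return 2.0 * (sinc @ h), float(d.min())

    def _chi(self, i_model: np.ndarray, fit_background: bool) -> float:
        exp = self.experiment
        w = 1.0 / exp.sigma
        mw, ew = i_model * w, exp.I * w
        if fit_background:
            a_mat = np.column_stack([mw, w])
            sol, *_ = np.linalg.lstsq(a_mat, ew, rcond=None)
            resid = ew - a_mat @ sol
        else:
            c = float(mw @ ew) / float(mw @ mw)
            resid = ew - c * mw
        chi = math.sqrt(float(resid @ resid) / len(ew))
        if not math.isfinite(chi):
            raise RuntimeError("non-finite chi during refinement; check sigma and model")
        return chi

    # -- the MC loop --------------------------------------------------------

    def fit(self, cfg: MCConfig | None = None) -> RefinementResult:
        cfg = cfg or MCConfig()
        a = self.assembly
        movable = list(cfg.moved_components) if cfg.moved_components is not None \
            else a.component_ids[1:]
        if not movable:
            raise StructureError("no movable components")
        rng = np.random.default_rng(cfg.seed)
        state, weights, intra, pairs, wprod, bins = self._setup(cfg)
        cross = {}
        min_d = {}
        for p in pairs:
            cross[p], min_d[p] = self._pair_term(state["coords"][p[0]],
                                                 state["coords"][p[1]], wprod[p], bins)
        current_chi = self._chi(intra + sum(cross.values()), cfg.fit_background)
        best_chi = current_chi
        best_transforms = dict(state["transforms"])
        best_coords = dict(state["coords"])
        trace: list[TraceStep] = []
        n_accepted = n_clashed = 0
        temp = cfg.temperature
        last_restart = 0
        for step in range(cfg.n_steps):
            if (cfg.restart_interval > 0 and step > 0
                    and step % cfg.restart_interval == 0):
                # restart the schedule from the best state found so far:
                # re-expanded moves give a fresh chance to leave a shallow
                # local minimum, then the decay narrows in again
                state["coords"] = dict(best_coords)
                state["transforms"] = dict(best_transforms)
                for p in pairs:
                    cross[p], min_d[p] = self._pair_term(
                        state["coords"][p[0]], state["coords"][p[1]], wprod[p], bins)
                current_chi = best_chi
                last_restart = step
            max_rot, max_trans = cfg.step_sizes(step - last_restart, rng)
            use_orbit = cfg.orbit_fraction > 0 and rng.random() < cfg.orbit_fraction
            if use_orbit:
                # orbit move: rotate one component rigidly about the centroid
                # of the remaining components.  The scattering pattern is
                # almost blind to the direction of one component relative to
                # the rest (orientational averaging), so this proposes steps
                # along that weakly-constrained manifold directly instead of
                # relying on chance correlation of rotation and translation.
                cid, rot, _ = _draw_move(movable, rng, max_rot, 0.0)
                c_self = state["coords"][cid].mean(axis=0)
                others = np.vstack([state["coords"][o] for o in a.component_ids
                                    if o != cid])
                rel = c_self - others.mean(axis=0)
                trans = rel @ rot.T - rel
            else:
                cid, rot, trans = _draw_move(movable, rng, max_rot, max_trans)
            old = state["coords"][cid]
            pivot = old.mean(axis=0)
            new_coords = (old - pivot) @ rot.T + pivot + trans
            new_cross, new_min = {}, {}
            for p in pairs:
                if cid not in p:
                    continue
                ca = new_coords if p[0] == cid else state["coords"][p[0]]
                cb = new_coords if p[1] == cid else state["coords"][p[1]]
                new_cross[p], new_min[p] = self._pair_term(ca, cb, wprod[p], bins)
            overall_min = min(new_min.get(p, min_d[p]) for p in pairs)
            if overall_min < cfg.clash_threshold:
                n_clashed += 1
                trace.append(TraceStep(step, float("nan"), False, True))
                temp *= cfg.anneal
                continue
            i_model = intra + sum(new_cross.get(p, cross[p]) for p in pairs)
            proposed_chi = self._chi(i_model, cfg.fit_background)
            delta = proposed_chi - current_chi
            accept = delta <= 0 or (temp > 0 and rng.random() < math.exp(-delta / temp))
            if accept:
                state["coords"][cid] = new_coords
                state["transforms"][cid] = state["transforms"][cid].compose_about(rot, trans)
                cross.update(new_cross)
                min_d.update(new_min)
                current_chi = proposed_chi
                n_accepted += 1
                if proposed_chi < best_chi:
                    best_chi = proposed_chi
                    best_transforms = dict(state["transforms"])
                    best_coords = dict(state["coords"])
            trace.append(TraceStep(step, proposed_chi, accept, False))
            temp *= cfg.anneal
        best = RigidBodyAssembly(a.components, best_transforms)
        return RefinementResult(
            best_assembly=best,
            best_chi=best_chi,
            start_chi=self._start_chi(cfg),
            trace=tuple(trace),
            n_accepted=n_accepted,
            n_clashed=n_clashed,
            config=cfg,
        )

    def _start_chi(self, cfg: MCConfig) -> float:
        a, q = self.assembly, self.experiment.q
        ids = a.component_ids
        coords = np.vstack([a.transformed_coords(cid) for cid in ids])
        w = np.concatenate([a.components[cid].weights for cid in ids])
        return self._chi(debye_intensity(coords, w, q), cfg.fit_background)


def mc_refine(a: RigidBodyAssembly, experiment: ScatteringCurve,
              cfg: MCConfig | None = None) -> RefinementResult:
    """Functional wrapper around :class:`RigidBodyModel`."""
    return RigidBodyModel(a, experiment).fit(cfg)


# ---------------------------------------------------------------------------
# Interface reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPair:
    component_a: str
    label_a: str
    component_b: str
    label_b: str
    distance: float


def interface_pairs(a: RigidBodyAssembly, cutoff: float) -> list[ContactPair]:
    """All inter-component centre pairs within ``cutoff`` A, sorted by
    distance (closest first)."""
    ids = a.component_ids
    coords = {cid: a.transformed_coords(cid) for cid in ids}
    out: list[ContactPair] = []
    for i, ci in enumerate(ids):
        labels_i = [c.label for c in a.components[ci].centres]
        for cj in ids[i + 1:]:
            labels_j = [c.label for c in a.components[cj].centres]
            d = cdist(coords[ci], coords[cj])
            for ii, jj in zip(*np.nonzero(d <= cutoff)):
                out.append(ContactPair(ci, labels_i[ii], cj, labels_j[jj],
                                       float(d[ii, jj])))
    return sorted(out, key=lambda p: p.distance)
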