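"""Synthetic fixture generators with known ground truth.

Three families cover the inputs the model needs end-to-end:

* ``make_chiral_dataset`` — single-stereocenter molecules for R/S
  classification. A carbon center carries four substituents with distinct,
  fixed elements (F > O > N > C by atomic number); the label is the sign of
  the signed volume det[s₁−c, s₂−c, s₃−c] of the three highest-priority
  substituents. This simplified priority rule has the same mirror-flip
  semantics as CIP R/S (reflection flips every label) and makes the label a
  deterministic function of geometric handedness, so the task is exactly
  learnable from the sign of the chirality-aware torsion features.
* ``make_equilibrium_set`` — spring-network molecules whose equilibrium
  minimizes a documented toy potential (harmonic bonds plus soft-core
  repulsion); a stand-in for force-field-optimized conformers that keeps the
  energy function available for evaluating relaxations.
* ``make_multitask_suite`` — a hypergraph-structured, partially annotated
  multi-task label set with mixed classification/regression tasks, auto-
  computed task meta-information, and a designated correlated task pair.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .io import smiles_to_conformer  # noqa: F401  (re-exported interface)
from .molgraph import Conformation, perturb_conformation
from .tmoe import TaskMeta
from .training import MultiTaskDataset, PropertyHypergraph

__all__ = ["ChiralMolecule", "SpringMolecule", "ToyPotential", "SyntheticTaskSuite",
           "make_chiral_dataset", "make_equilibrium_set", "make_multitask_suite",
           "chiral_label", "smiles_to_conformer"]

# fixed substituent elements, priority = atomic number: F(9) > O(8) > N(7) > C(6)
_SUBSTITUENT_Z = (9, 8, 7, 6)
_MIN_SIGNED_VOLUME = 0.05  # Å³; near-planar centers rejected

# Fixed chiral substituent-direction template. A regular tetrahedron is an
# achiral shape (every pseudoscalar vanishes on it), so the torsion signal at
# a symmetric center would be pure jitter noise; this template is strongly
# chiral — the torsion at every center edge is bounded away from zero — so
# geometric handedness is carried with a margin. Elements are tied to slots,
# which couples the R/S label (a priority-ordered signed volume) to the
# template's handedness.
_CHIRAL_TEMPLATE = np.array([
    [-0.4394, 0.1410, -0.8871],   # slot F
    [0.3028, -0.9008, 0.3112],    # slot O
    [0.5695, 0.7943, -0.2117],    # slot N
    [-0.5315, 0.3336, 0.7786],    # slot C (chain attachment)
])
_CHIRAL_TEMPLATE /= np.linalg.norm(_CHIRAL_TEMPLATE, axis=1, keepdims=True)

#: graph cutoff (Å) under which the generated core has fixed neighbor sets:
#: all center–substituent and substituent–substituent pairs fall inside it,
#: all chain atoms stay outside the core's radius.
CHIRAL_CUTOFF = 2.75
_DIR_JITTER = 0.04            # direction noise before re-normalization
_BOND_RANGE = (1.42, 1.48)    # center–substituent bond lengths (Å)
_SUBSUB_RANGE = (1.95, 2.65)  # admissible substituent–substituent distances
_MIN_PSI_MARGIN = 0.05        # reject near-degenerate torsion at the F edge


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def chiral_label(conf: Conformation, center: int = 0) -> str:
    """R/S label by signed volume under the package's priority rule.

    The three substituents of highest priority (atomic number descending,
    ties broken by atom index) span the oriented triple whose determinant's
    sign defines the label: positive → R, negative → S.
    """
    subs = np.arange(1, 5) if center == 0 else None
    if subs is None:
        raise ValueError("stereocenter must be atom 0 of a generated chiral molecule")
    order = sorted(subs, key=lambda i: (-int(conf.elements[i]), i))[:3]
    c = conf.positions[center]
    vol = np.linalg.det(conf.positions[order] - c)
    if abs(vol) <= _MIN_SIGNED_VOLUME:
        raise ValueError("degenerate (near-planar) stereocenter")
    return "R" if vol > 0 else "S"


@dataclass
class ChiralMolecule:
    """A conformation with one tetrahedral stereocenter and its R/S label."""
    conformation: Conformation
    label: str

    def mirrored(self) -> "ChiralMolecule":
        """The exact enantiomer: reflected geometry, flipped label."""
        return ChiralMolecule(self.conformation.mirrored(),
                              "S" if self.label == "R" else "R")


def _psi_at_f_edge(conf: Conformation) -> float:
    """Torsion at the directed center→F edge under the core cutoff."""
    from .molgraph import build_graph
    from .se3 import chirality_vectors, torsion_angles

    graph = build_graph(conf, cutoff=CHIRAL_CUTOFF)
    tf = torsion_angles(chirality_vectors(graph), graph)
    e = np.nonzero((graph.edges[:, 0] == 0) & (graph.edges[:, 1] == 1))[0][0]
    return float(tf.psi[e])


def _one_chiral_molecule(rng: np.random.Generator, n_extra: int) -> Conformation:
    while True:
        R = _random_rotation(rng)
        dirs = (_CHIRAL_TEMPLATE + rng.normal(0.0, _DIR_JITTER, size=(4, 3))) @ R.T
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        bond = rng.uniform(*_BOND_RANGE, size=4)
        subs = dirs * bond[:, None]
        dd = pdist(subs)
        # keep the core inside the cutoff with fixed neighbor sets
        if dd.min() < _SUBSUB_RANGE[0] or dd.max() > _SUBSUB_RANGE[1]:
            continue
        if abs(np.linalg.det(subs[:3])) <= _MIN_SIGNED_VOLUME:
            continue
        positions = [np.zeros(3), *subs]
        elements = [6, *_SUBSTITUENT_Z]
        # decorate the lowest-priority substituent with an outward carbon
        # chain kept clear of the stereocenter core
        tip = subs[3]
        prev_dir = subs[3] / np.linalg.norm(subs[3])
        ok = True
        for _ in range(n_extra):
            for _attempt in range(80):
                step = prev_dir + rng.normal(0.0, 0.25, size=3)
                step /= np.linalg.norm(step)
                cand = tip + 1.5 * step
                if (all(np.linalg.norm(cand - p) > 1.2 for p in positions[4:])
                        and all(np.linalg.norm(cand - positions[i]) > 2.8
                                for i in range(4))):
                    break
            else:
                ok = False
                break
            positions.append(cand)
            elements.append(6)
            prev_dir, tip = step, cand
        if not ok:
            continue
        conf = Conformation(np.array(elements), np.array(positions))
        if abs(_psi_at_f_edge(conf)) < _MIN_PSI_MARGIN:
            continue  # near-degenerate handedness signal; resample
        return conf


def make_chiral_dataset(n: int, seed: int) -> list[ChiralMolecule]:
    """n single-stereocenter molecules (5–12 heavy atoms), classes balanced.

    The desired label alternates; a molecule whose sampled geometry has the
    wrong handedness is reflected, so class counts differ by at most one.
    """
    rng = np.random.default_rng(seed)
    out: list[ChiralMolecule] = []
    for k in range(n):
        conf = _one_chiral_molecule(rng, int(rng.integers(0, 8)))
        label = chiral_label(conf)
        want = "R" if k % 2 == 0 else "S"
        if label != want:
            conf = conf.mirrored()
            label = chiral_label(conf)
        conf.mol_id = f"chiral-{k}"
        out.append(ChiralMolecule(conf, label))
    return out


class ToyPotential:
    """Harmonic springs on a bond graph plus soft-core pair repulsion.

    E(P) = Σ_bonds k/2 (r_b − r0_b)² + Σ_{i<j} c_rep (r_c − r_ij)² [r_ij < r_c]

    Units are arbitrary (coordinates in Å); defaults give bond rest lengths
    near 1.5 Å and a repulsion core of 1.0 Å so equilibria look molecular.
    """

    def __init__(self, bonds: np.ndarray, rest_lengths: np.ndarray,
                 k_spring: float = 10.0, c_rep: float = 5.0, r_core: float = 1.0):
        self.bonds = np.asarray(bonds, dtype=np.int64)
        self.rest_lengths = np.asarray(rest_lengths, dtype=np.float64)
        self.k_spring = k_spring
        self.c_rep = c_rep
        self.r_core = r_core

    def energy(self, positions: np.ndarray) -> float:
        return self.energy_and_gradient(positions)[0]

    def energy_and_gradient(self, positions: np.ndarray):
        P = np.asarray(positions, dtype=np.float64)
        n = len(P)
        grad = np.zeros_like(P)
        d = P[self.bonds[:, 0]] - P[self.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        e = 0.5 * self.k_spring * ((r - self.rest_lengths) ** 2).sum()
        f = (self.k_spring * (r - self.rest_lengths) / r)[:, None] * d
        np.add.at(grad, self.bonds[:, 0], f)
        np.add.at(grad, self.bonds[:, 1], -f)
        iu, ju = np.triu_indices(n, k=1)
        dp = P[iu] - P[ju]
        rp = np.linalg.norm(dp, axis=1)
        close = rp < self.r_core
        if close.any():
            gap = self.r_core - rp[close]
            e += self.c_rep * (gap**2).sum()
            fp = (-2.0 * self.c_rep * gap / rp[close])[:, None] * dp[close]
            np.add.at(grad, iu[close], fp)
            np.add.at(grad, ju[close], -fp)
        return float(e), grad

    def __call__(self, positions: np.ndarray) -> float:
        return self.energy(positions)


@dataclass
class SpringMolecule:
    conformation: Conformation   # equilibrium stored; positions may be perturbed
    potential: ToyPotential


# Bond rest lengths (Å) by element pair, mimicking covalent radii: the rest
# length is a deterministic function of the bonded atom types, so a model
# that sees elements and geometry can infer whether a bond is stretched or
# compressed — the same observability a real force field provides.
_REST_LENGTH = {
    (6, 6): 1.54, (6, 7): 1.47, (6, 8): 1.43,
    (7, 7): 1.45, (7, 8): 1.40, (8, 8): 1.48,
}


def bond_rest_length(z1: int, z2: int) -> float:
    return _REST_LENGTH[tuple(sorted((int(z1), int(z2))))]


def _random_bond_graph(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random connected graph: random spanning tree plus a few chords."""
    bonds = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    existing = set(bonds)
    for _ in range(int(rng.integers(0, max(1, n // 3) + 1))):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if i != j and (int(i), int(j)) not in existing:
            bonds.append((int(i), int(j)))
            existing.add((int(i), int(j)))
    return np.array(bonds, dtype=np.int64)


def make_equilibrium_set(n_molecules: int, n_atoms_range: tuple[int, int] = (6, 12),
                         seed: int = 0, sigma: float = 0.0,
                         grad_tol: float = 1e-4) -> list[SpringMolecule]:
    """Spring-network molecules minimized to ‖∇E‖∞ < grad_tol.

    With ``sigma > 0`` each returned conformation is additionally perturbed
    by Gaussian coordinate noise (the equilibrium is retained on the
    conformation for supervision).
    """
    rng = np.random.default_rng(seed)
    out: list[SpringMolecule] = []
    for k in range(n_molecules):
        n = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
        bonds = _random_bond_graph(n, rng)
        elements = rng.choice([6, 7, 8], size=n, p=[0.7, 0.15, 0.15])
        rest = np.array([bond_rest_length(elements[i], elements[j])
                         for i, j in bonds])
        pot = ToyPotential(bonds, rest)
        for _attempt in range(20):
            x0 = rng.normal(0.0, 0.8 * n ** (1 / 3), size=(n, 3))
            def fun(x):
                e, g = pot.energy_and_gradient(x.reshape(n, 3))
                return e, g.ravel()

            res = minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                           options={"gtol": grad_tol * 1e-2, "maxiter": 2000})
            eq = res.x.reshape(n, 3)
            if np.abs(pot.energy_and_gradient(eq)[1]).max() < grad_tol:
                break
        else:
            raise RuntimeError(f"minimization failed for molecule {k}")
        conf = Conformation(elements, eq.copy(), equilibrium_positions=eq.copy(),
                            perturbation=np.zeros_like(eq), mol_id=f"spring-{k}")
        if sigma > 0:
            conf = perturb_conformation(conf, sigma, rng)
            conf.mol_id = f"spring-{k}"
        out.append(SpringMolecule(conf, pot))
    return out


@dataclass
class SyntheticTaskSuite:
    dataset: MultiTaskDataset
    coverage: dict               # task_id -> realized labeled fraction
    correlated_pair: tuple       # (task_id, task_id) sharing a latent score

    @property
    def hypergraph(self) -> PropertyHypergraph:
        return self.dataset.hypergraph


def _radius_of_gyration(conf: Conformation) -> float:
    centered = conf.positions - conf.positions.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def _heteroatom_fraction(conf: Conformation) -> float:
    return float((conf.elements != 6).mean())


def make_multitask_suite(n_molecules: int, n_tasks: int, coverage: float,
                         seed: int = 0, sigma: float = 0.3) -> SyntheticTaskSuite:
    """Hypergraph-structured multi-task labels over spring-network molecules.

    Tasks are deterministic functions of geometry/composition: task 0 is a
    classification of the radius of gyration against its median; tasks 1 and
    2 are regressions of the same latent score (the designated correlated
    pair); further tasks alternate classification (heteroatom fraction
    thresholds) and regression (noisy linear reads of the latents). Each task
    labels a uniformly sampled subset of round(coverage·n) molecules, and
    TaskMeta statistics (η, μ, σ) are computed from the realized labels.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if n_tasks < 1:
        raise ValueError("need at least one task")
    rng = np.random.default_rng(seed)
    springs = make_equilibrium_set(n_molecules, seed=seed + 1, sigma=sigma)
    molecules = [s.conformation for s in springs]
    rg = np.array([_radius_of_gyration(c) for c in molecules])
    het = np.array([_heteroatom_fraction(c) for c in molecules])
    latents = {"rg": rg, "het": het}

    n_labeled = int(round(coverage * n_molecules))
    tasks: list[TaskMeta] = []
    labels: dict[int, dict[int, float]] = {}
    groups = ("physicochemical", "absorption", "distribution", "metabolism",
              "excretion", "toxicity")
    for tid in range(n_tasks):
        subset = np.sort(rng.choice(n_molecules, size=n_labeled, replace=False))
        group = groups[tid % len(groups)]
        if tid == 0 or (tid >= 3 and tid % 2 == 1):
            z = rg if tid == 0 else het + 0.05 * rng.normal(size=n_molecules)
            y = (z > np.median(z)).astype(float)
            vals = {int(i): float(y[i]) for i in subset}
            eta = float(np.mean(list(vals.values())))
            eta = min(max(eta, 1e-6), 1 - 1e-6)
            tasks.append(TaskMeta(task_id=tid, task_type="classification",
                                  group=group, name=f"task{tid}", positive_ratio=eta))
        else:
            base = rg if tid in (1, 2) else (rg if tid % 4 == 0 else het)
            noise_scale = 0.05 if tid in (1, 2) else 0.2
            y = base + noise_scale * rng.normal(size=n_molecules)
            vals = {int(i): float(y[i]) for i in subset}
            arr = np.array(list(vals.values()))
            tasks.append(TaskMeta(task_id=tid, task_type="regression", group=group,
                                  name=f"task{tid}", target_mean=float(arr.mean()),
                                  target_std=float(arr.std(ddof=0)) or 1.0))
        labels[tid] = vals
    dataset = MultiTaskDataset(molecules=molecules, tasks=tasks, labels=labels)
    cov = {tid: len(labels[tid]) / n_molecules for tid in labels}
    return SyntheticTaskSuite(dataset=dataset, coverage=cov,
                              correlated_pair=(1, 2) if n_tasks >= 3 else (0, 0))
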