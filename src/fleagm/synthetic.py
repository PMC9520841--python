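"""Synthetic data with the statistical structure of a two-species flea survey.

Generators for (i) landmark datasets of flea heads — a 13-point template
(5 fixed points plus a resampled head-outline arc) perturbed along fixed
tangent-space effect directions for species, sex and their interaction,
with isotropic Gaussian landmark noise and random nuisance similarity
transforms; (ii) cox1 sequence sets with a designed haplotype frequency
spectrum and species divergences planted as exact Kimura-2-parameter
substitution counts; (iii) observer confusion processes for morphological
identification; and (iv) per-dog survey tables.

Defaults emulate the study conditions the analysis is meant for: landmark
group sizes (86, 26, 45, 8) for (canis F, canis M, orientis F, orientis M),
a 25-haplotype cox1 spectrum over 166 sequences (22 canis + 3 orientis
haplotypes), species-level morphological misidentification of C. orientis
around 31% (females) and 57% (males), and a 77-dog survey at 56%
infestation prevalence.  All generators are bit-reproducible given seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tps import LandmarkSpecimen
from .molecular import SequenceRecord, k2p_inverse
from .shape_core import ShapeDataset

__all__ = [
    "ShapeSimSpec",
    "SeqSimSpec",
    "ConfusionSpec",
    "head_template",
    "simulate_landmark_dataset",
    "landmark_dataset_to_specimens",
    "simulate_cox1_dataset",
    "simulate_reference_panel",
    "simulate_observer_ids",
    "simulate_survey",
    "evolve_k80",
    "REGIONS",
]

REGIONS = ["Jizzax", "Buxoro", "Fargona", "Samarkand", "Surkxandaryo"]

# canis: 22 haplotypes over 113 sequences; orientis: 3 over 53 (166 total)
DEFAULT_HAPLOTYPE_DESIGN = [
    ("canis", [56, 20, 7, 2, 2, 1, 1, 7, 1, 1, 2, 1, 1, 1, 1, 1, 1, 2, 1, 2, 1, 1]),
    ("orientis", [25, 18, 10]),
]

DEFAULT_CONFUSION = {
    "canis:F": {"canis": 0.84, "orientis": 0.06, "indeterminate": 0.10},
    "canis:M": {"canis": 0.81, "orientis": 0.09, "indeterminate": 0.10},
    "orientis:F": {"orientis": 0.59, "canis": 0.31, "indeterminate": 0.10},
    "orientis:M": {"orientis": 0.33, "canis": 0.57, "indeterminate": 0.10},
}


def head_template(n_arc: int = 10) -> np.ndarray:
    """13-point flea-head template: 5 anchor points + interior arc semilandmarks.

    The head outline is a half-circle from the top anchor (point 0) to the
    bottom anchor (point 4); resampling it into ``n_arc`` points and
    merging the two endpoints with those anchors leaves ``n_arc - 2``
    interior semilandmarks, 13 points in total for the default scheme.
    The geometry is a stand-in fixture: it mimics the proportions of a
    digitised head, not any particular specimen.
    """
    fixed = np.array(
        [
            [0.0, 1.0],  # top of head (curve start)
            [0.8, 0.5],
            [0.9, -0.1],
            [0.5, -0.8],
            [0.0, -1.0],  # bottom of head (curve end)
        ]
    )
    angles = np.linspace(np.pi / 2.0, 3.0 * np.pi / 2.0, n_arc)[1:-1]
    arc = np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([fixed, arc])


@dataclass
class ShapeSimSpec:
    """Study conditions for the landmark generator.

    Effect magnitudes are tangent-space displacements in Procrustes units
    (the template has unit centroid size); ``landmark_noise_sd`` is the
    per-coordinate isotropic Gaussian sigma.  Group sizes are ordered
    (canis F, canis M, orientis F, orientis M).
    """

    template: np.ndarray = field(default_factory=head_template)
    species_effect: float = 0.015
    sex_effect: float = 0.018
    interaction_effect: float = 0.004
    landmark_noise_sd: float = 0.01
    group_sizes: tuple[int, int, int, int] = (86, 26, 45, 8)
    rotation_range: tuple[float, float] = (-np.pi, np.pi)
    translation_range: tuple[float, float] = (-100.0, 100.0)
    scale_range: tuple[float, float] = (50.0, 200.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.species_effect, self.sex_effect, self.interaction_effect) < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if self.landmark_noise_sd <= 0:
            raise ValueError("landmark noise sigma must be > 0")
        if min(self.group_sizes) < 0:
            raise ValueError("group sizes must be >= 0")


def _nuisance_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-nuisance directions at a pre-shape."""
    p = len(template)
    centred = template - template.mean(axis=0)
    z = centred / np.sqrt(np.sum(centred**2))
    tx = np.tile([1.0, 0.0], p) / np.sqrt(p)
    ty = np.tile([0.0, 1.0], p) / np.sqrt(p)
    scale_dir = z.reshape(-1)
    rot_dir = (z @ np.array([[0.0, 1.0], [-1.0, 0.0]])).reshape(-1)
    B = np.stack([tx, ty, scale_dir, rot_dir / np.linalg.norm(rot_dir)])
    q, _ = np.linalg.qr(B.T)
    return q  # (2p, 4)


def _effect_directions(template: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Three orthonormal tangent-space directions free of nuisance components."""
    p = len(template)
    N = _nuisance_basis(template)
    raw = rng.standard_normal((2 * p, 3))
    raw -= N @ (N.T @ raw)
    q, _ = np.linalg.qr(raw)
    return q[:, :3]  # columns: species, sex, interaction


def simulate_landmark_dataset(
    spec: ShapeSimSpec,
) -> tuple[ShapeDataset, dict[str, np.ndarray]]:
    """Generate a labelled 2-species x 2-sex landmark dataset.

    Each specimen is the template pre-shape displaced by
    ``+/- species_effect * u_sp +/- sex_effect * u_sex +/- interaction * u_int``
    (sign +1 for orientis / males / same-sign cells) plus per-coordinate
    Gaussian noise, then hit with a random rotation, translation and scale.
    Returns the dataset and the true effect unit vectors for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    template = np.asarray(spec.template, dtype=float)
    centred = template - template.mean(axis=0)
    z = centred / np.sqrt(np.sum(centred**2))
    U = _effect_directions(template, rng)
    u_sp, u_sex, u_int = U[:, 0], U[:, 1], U[:, 2]
    p = len(template)

    cells = [("canis", "F"), ("canis", "M"), ("orientis", "F"), ("orientis", "M")]
    configs = []
    rows = []
    i = 0
    for (species, sex), size in zip(cells, spec.group_sizes):
        s_sp = 1.0 if species == "orientis" else -1.0
        s_sex = 1.0 if sex == "M" else -1.0
        mean_shape = (
            z.reshape(-1)
            + s_sp * spec.species_effect * u_sp
            + s_sex * spec.sex_effect * u_sex
            + s_sp * s_sex * spec.interaction_effect * u_int
        ).reshape(p, 2)
        for _ in range(size):
            shape = mean_shape + rng.normal(0.0, spec.landmark_noise_sd, size=(p, 2))
            theta = rng.uniform(*spec.rotation_range)
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            scale = rng.uniform(*spec.scale_range)
            shift = rng.uniform(*spec.translation_range, size=2)
            configs.append(scale * shape @ R.T + shift)
            rows.append(
                {
                    "specimen_id": f"FL{i:03d}",
                    "species": species,
                    "sex": sex,
                    "region": REGIONS[i % len(REGIONS)],
                }
            )
            i += 1
    dataset = ShapeDataset(
        configurations=np.stack(configs), labels=pd.DataFrame(rows)
    )
    truth = {"species": u_sp, "sex": u_sex, "interaction": u_int}
    return dataset, truth


def landmark_dataset_to_specimens(dataset: ShapeDataset) -> list[LandmarkSpecimen]:
    """Express 13-point configurations as TPS specimens (5 landmarks + head curve).

    The curve polyline runs from fixed point 0 through the 8 interior
    semilandmarks to fixed point 4, so resampling it into 10 points merges
    its two endpoints back onto those fixed landmarks.
    """
    specimens = []
    for i, pts in enumerate(dataset.configurations):
        if pts.shape[0] != 13:
            raise ValueError("expected 13-point configurations (5 fixed + 8 arc)")
        curve = np.vstack([pts[0], pts[5:], pts[4]])
        labels = dataset.labels.iloc[i]
        specimens.append(
            LandmarkSpecimen(
                specimen_id=str(labels["specimen_id"]),
                landmarks=pts[:5].copy(),
                curves=[curve],
                labels={
                    "sex": labels["sex"],
                    "species_cox1": labels["species"],
                    "region": labels["region"],
                },
            )
        )
    return specimens


# ---------------------------------------------------------------------------
# cox1 sequences


@dataclass
class SeqSimSpec:
    """Study conditions for the cox1 generator.

    ``haplotype_design`` lists per species the multiplicity of each
    haplotype; ``within_species_max_divergence`` is the K2P distance of the
    two most divergent haplotypes within a species; founder sequences sit
    ``between_species_divergence`` apart.  Substitution counts are solved
    exactly from the K2P inversion at transition/transversion ratio kappa.
    """

    ancestor_length: int = 614
    haplotype_design: list[tuple[str, list[int]]] = field(
        default_factory=lambda: [(sp, list(m)) for sp, m in DEFAULT_HAPLOTYPE_DESIGN]
    )
    within_species_max_divergence: dict[str, float] = field(
        default_factory=lambda: {"canis": 0.012, "orientis": 0.064}
    )
    between_species_divergence: float = 0.12
    ts_tv_ratio: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ancestor_length < 100:
            raise ValueError("ancestor length must be >= 100")
        if not 0 < self.between_species_divergence < 0.7:
            raise ValueError("between-species divergence must be in (0, 0.7)")
        for sp, mult in self.haplotype_design:
            if any(m < 1 for m in mult):
                raise ValueError(f"multiplicities for {sp!r} must be >= 1")


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _plant_substitutions(
    seq: list[str], sites: np.ndarray, n_ts: int, rng: np.random.Generator
) -> None:
    """Mutate ``seq`` in place: first ``n_ts`` sites get transitions, the rest transversions."""
    for k, site in enumerate(sites):
        base = seq[site]
        if k < n_ts:
            seq[site] = _TS_PARTNER[base]
        else:
            seq[site] = _TV_PARTNERS[base][rng.integers(2)]


def _counts_for(d: float, L: int, ratio: float) -> tuple[int, int]:
    P, Q = k2p_inverse(d, ratio)
    return int(round(P * L)), int(round(Q * L))


def simulate_cox1_dataset(
    spec: SeqSimSpec,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Generate cox1 amplicons with a designed haplotype spectrum.

    A random ancestor seeds one founder per species (planted at the
    between-species divergence); within each species, haplotypes radiate
    from the founder at mutually disjoint substitution sites so that the
    two most divergent haplotypes sit at the within-species target.  Each
    haplotype is replicated per its multiplicity.  Returns the records and
    the true haplotype membership (haplotype key -> member seq ids).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_length
    ancestor = rng.choice(list("ACGT"), size=L)
    free_sites = list(rng.permutation(L))  # globally disjoint substitution sites

    def take(n: int) -> np.ndarray:
        if n > len(free_sites):
            raise ValueError(
                "divergence targets require more substitution sites than the "
                "sequence length allows"
            )
        out = np.array([free_sites.pop() for _ in range(n)], dtype=int)
        return out

    records: list[SequenceRecord] = []
    membership: dict[str, list[str]] = {}
    seq_counter = 0
    for sp_index, (species, mult) in enumerate(spec.haplotype_design):
        founder = list(ancestor)
        if sp_index > 0:
            n_ts, n_tv = _counts_for(spec.between_species_divergence, L, spec.ts_tv_ratio)
            _plant_substitutions(founder, take(n_ts + n_tv), n_ts, rng)
        target = spec.within_species_max_divergence.get(species, 0.0)
        n_haps = len(mult)
        hap_seqs = [founder]
        if n_haps > 1:
            x_ts, x_tv = _counts_for(target, L, spec.ts_tv_ratio)
            x = max(x_ts + x_tv, 2 if n_haps > 2 else 1)
            budgets = [x - x // 2, x // 2]  # the two extreme haplotypes
            for _ in range(n_haps - 3):
                budgets.append(int(rng.integers(1, max(2, x // 2 + 1))))
            for j, budget in enumerate(budgets[: n_haps - 1]):
                frac_ts = x_ts / max(1, x_ts + x_tv)
                n_ts_j = int(round(budget * frac_ts))
                hap = list(founder)
                _plant_substitutions(hap, take(budget), n_ts_j, rng)
                hap_seqs.append(hap)
        for j, (seq, m) in enumerate(zip(hap_seqs, mult)):
            key = f"{species}_hap{j + 1}"
            membership[key] = []
            for _ in range(m):
                sid = f"UZB{seq_counter:03d}"
                seq_counter += 1
                records.append(
                    SequenceRecord(seq_id=sid, sequence="".join(seq), species=species)
                )
                membership[key].append(sid)
    return records, membership


def simulate_reference_panel(
    records: list[SequenceRecord],
    *,
    n_panel: int = 90,
    n_matched: dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Build a reference haplotype panel (h1...hN) containing some dataset haplotypes.

    ``n_matched`` haplotypes per species (default 4 canis + 1 orientis,
    chosen among the dataset's distinct sequences) are copied into the
    panel verbatim; the remaining panel entries are distinct variants
    mutated away from dataset sequences.  Returns the panel and the map
    dataset-sequence -> panel id for the planted matches.
    """
    if n_matched is None:
        n_matched = {"canis": 4, "orientis": 1}
    rng = np.random.default_rng(seed)
    uniq: dict[str, str] = {}
    for r in records:
        uniq.setdefault(r.sequence, r.species)
    by_species: dict[str, list[str]] = {}
    for seq, sp in uniq.items():
        by_species.setdefault(sp, []).append(seq)
    panel: list[SequenceRecord] = []
    matches: dict[str, str] = {}
    idx = 1
    for sp, k in n_matched.items():
        seqs = by_species.get(sp, [])
        chosen = [seqs[i] for i in rng.choice(len(seqs), size=min(k, len(seqs)), replace=False)]
        for seq in chosen:
            pid = f"h{idx}"
            idx += 1
            panel.append(SequenceRecord(seq_id=pid, sequence=seq, species=sp))
            matches[seq] = pid
    template = records[0].sequence
    dataset_seqs = set(uniq)
    while len(panel) < n_panel:
        hap = list(template)
        sites = rng.choice(len(hap), size=int(rng.integers(12, 30)), replace=False)
        _plant_substitutions(hap, sites, int(len(sites) * 2 / 3), rng)
        s = "".join(hap)
        if s in dataset_seqs:
            continue
        panel.append(SequenceRecord(seq_id=f"h{idx}", sequence=s, species="unknown"))
        idx += 1
    return panel, matches


def evolve_k80(
    sequence: str, distance: float, kappa: float = 2.0, rng: np.random.Generator | None = None
) -> str:
    """Evolve a sequence for ``distance`` expected substitutions/site under K80.

    Uses the exact Kimura-2-parameter transition probability matrix at the
    given branch length with transition/transversion *rate* ratio kappa;
    every site is drawn independently.  This is the stochastic counterpart
    of the exact-count planting used by the dataset generator, and is what
    distance-estimator recovery checks sample from.
    """
    if rng is None:
        rng = np.random.default_rng()
    # rate matrix scaled to one expected substitution per unit distance:
    # alpha = transition rate, beta = each transversion rate, kappa = alpha/beta
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    t = distance
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv_each = 0.25 * (1.0 - e1)  # each of the two transversion targets
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    out = []
    for base in sequence.upper():
        if base not in _TS_PARTNER:
            out.append(base)
            continue
        u = rng.random()
        if u < p_same:
            out.append(base)
        elif u < p_same + p_ts:
            out.append(_TS_PARTNER[base])
        else:
            tv = _TV_PARTNERS[base]
            out.append(tv[0] if u < p_same + p_ts + p_tv_each else tv[1])
    return "".join(out)


# ---------------------------------------------------------------------------
# observer confusion and survey


@dataclass
class ConfusionSpec:
    """Per-true-class probability vectors over assigned classes (rows sum to 1)."""

    probabilities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONFUSION.items()}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for cls, row in self.probabilities.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities for class {cls!r} sum to {total}, not 1")


def simulate_observer_ids(truth: "list[str] | np.ndarray", spec: ConfusionSpec) -> np.ndarray:
    """Independent draws of an observer's assigned class for each true class label."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for cls in truth:
        if cls not in spec.probabilities:
            raise ValueError(f"no confusion row for true class {cls!r}")
        row = spec.probabilities[cls]
        choices = list(row)
        out.append(rng.choice(choices, p=[row[c] for c in choices]))
    return np.array(out, dtype=object)


def simulate_survey(
    n_dogs: int = 77,
    infestation_p: float = 43 / 77,
    composition: dict[str, float] | None = None,
    *,
    mean_fleas_per_dog: float = 4.6,
    flea_female_p: float = 0.8,
    confusion: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
):
    """Generate a per-dog survey table.

    Infestation is Bernoulli per dog; flea counts on infested dogs follow a
    zero-truncated geometric with the given mean; species and flea sex are
    drawn from the composition; regions are assigned round-robin over the
    five survey locations.
    """
    from .survey_stats import SurveyTable

    if composition is None:
        composition = {"canis": 0.58, "orientis": 0.27, "irritans": 0.11, "unidentified": 0.04}
    if confusion is None:
        confusion = DEFAULT_CONFUSION
    total = sum(composition.values())
    species = list(composition)
    probs = np.array([composition[s] / total for s in species])
    rng = np.random.default_rng(seed)
    dog_rows = []
    flea_rows = []
    geo_p = min(1.0, 1.0 / mean_fleas_per_dog)
    for i in range(n_dogs):
        dog_id = f"D{i:03d}"
        infested = bool(rng.random() < infestation_p)
        dog_rows.append(
            {
                "dog_id": dog_id,
                "region": REGIONS[i % len(REGIONS)],
                "age_months": float(rng.integers(6, 27)),
                "dog_sex": "F" if rng.random() < 0.5 else "M",
                "infested": infested,
            }
        )
        if not infested:
            continue
        n_fleas = int(rng.geometric(geo_p))  # geometric on {1, 2, ...}: zero-truncated
        for _ in range(n_fleas):
            sp = species[rng.choice(len(species), p=probs)]
            flea_sex = "F" if rng.random() < flea_female_p else "M"
            # the morphological call carries observer confusion for the two
            # Ctenocephalides species; other species are keyed by eye
            row = confusion.get(f"{sp}:{flea_sex}")
            if row is not None:
                choices = list(row)
                morph = str(rng.choice(choices, p=[row[c] for c in choices]))
            else:
                morph = sp
            flea_rows.append(
                {
                    "dog_id": dog_id,
                    "species": sp,
                    "flea_sex": flea_sex,
                    "morphology_id": morph,
                    "cox1_id": sp if sp in ("canis", "orientis") else "unknown",
                }
            )
    return SurveyTable(
        dogs=pd.DataFrame(dog_rows),
        fleas=pd.DataFrame(
            flea_rows, columns=["dog_id", "species", "flea_sex", "morphology_id", "cox1_id"]
        ),
    )
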