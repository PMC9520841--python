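"""End-to-end pipeline stages wiring file I/O to the analysis modules.

Each stage reads standard text formats (TPS landmarks plus a labels TSV,
FASTA sequences, a survey TSV), runs the corresponding analysis and writes
TSV/newick outputs into an output directory.  Every stage logs the sample
sizes, seeds and permutation counts in effect, and identical configuration
plus seed yields byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tps, molecular, shape_core, shape_stats, survey_stats, synthetic

__all__ = ["RunConfig", "run_morphometrics", "run_molecular", "run_survey", "simulate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, seeds and flags for a pipeline run."""

    out_dir: Path
    tps_path: Path | None = None
    labels_path: Path | None = None
    fasta_path: Path | None = None
    panel_path: Path | None = None
    survey_path: Path | None = None
    seed: int = 0
    n_perm_cva: int = 10_000
    n_perm_dfa: int = 10_000
    bootstrap_reps: int = 1000
    flip_y: bool = False
    apply_scale: bool = False
    haplotype_mode: str = "full_length"
    ci_method: str = "wald"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("tps_path", "labels_path", "fasta_path", "panel_path", "survey_path"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if not value.exists():
                    raise FileNotFoundError(f"{name}: {value} does not exist")
        self.out_dir.mkdir(parents=True, exist_ok=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_morphometrics(config: RunConfig) -> dict[str, Path]:
    """TPS landmarks -> GPA -> Procrustes ANOVA -> CVA -> per-sex DFA with LOO."""
    if config.tps_path is None or config.labels_path is None:
        raise ValueError("morphometrics stage needs tps_path and labels_path")
    specimens = io_tps.read_tps(
        config.tps_path, apply_scale=config.apply_scale, flip_y=config.flip_y
    )
    if not specimens:
        raise ValueError(f"no specimens in {config.tps_path}")
    labels = pd.read_csv(config.labels_path, sep="\t", dtype=str)
    labels = labels.set_index("specimen_id")
    configs, ids = [], []
    for sp in specimens:
        configs.append(io_tps.build_configuration(sp))
        ids.append(sp.specimen_id)
    lab = labels.loc[ids].reset_index()
    dataset = shape_core.ShapeDataset.from_configurations(configs, lab)
    logger.info(
        "morphometrics: n=%d specimens, p=%d landmarks, seed=%d, n_perm_cva=%d, n_perm_dfa=%d",
        dataset.n, dataset.p, config.seed, config.n_perm_cva, config.n_perm_dfa,
    )
    gpa_res = shape_core.gpa(dataset)
    design = shape_stats.FactorialDesign.from_labels(lab)
    anova = shape_stats.procrustes_anova(gpa_res.tangent, design)
    groups = design.cells()
    cva_res = shape_stats.cva(
        gpa_res.tangent, groups, n_perm=config.n_perm_cva, seed=config.seed
    )
    out = {}
    out["anova"] = config.out_dir / "procrustes_anova.tsv"
    _write(anova.set_index("effect"), out["anova"])
    out["gpa"] = config.out_dir / "gpa_summary.tsv"
    _write(
        pd.DataFrame(
            {
                "specimen_id": ids,
                "centroid_size": gpa_res.centroid_sizes,
                "procrustes_to_mean": gpa_res.procrustes_to_mean,
            }
        ).set_index("specimen_id"),
        out["gpa"],
    )
    out["cva_scores"] = config.out_dir / "cva_scores.tsv"
    scores = pd.DataFrame(
        cva_res.scores, columns=[f"CV{i+1}" for i in range(cva_res.scores.shape[1])]
    )
    scores.insert(0, "group", groups)
    scores.insert(0, "specimen_id", ids)
    _write(scores.set_index("specimen_id"), out["cva_scores"])
    out["cva_eigen"] = config.out_dir / "cva_eigenvalues.tsv"
    _write(
        pd.DataFrame(
            {
                "eigenvalue": cva_res.eigenvalues,
                "percent_variance": cva_res.percent_variance,
            },
            index=[f"CV{i+1}" for i in range(len(cva_res.eigenvalues))],
        ),
        out["cva_eigen"],
    )
    out["cva_distances"] = config.out_dir / "cva_distances.tsv"
    dist = pd.concat(
        {
            "mahalanobis": cva_res.mahalanobis,
            "procrustes": cva_res.procrustes,
            "p_mahalanobis": cva_res.p_mahalanobis,
            "p_procrustes": cva_res.p_procrustes,
        }
    )
    _write(dist, out["cva_distances"])
    for sex in ("F", "M"):
        sel = lab["sex"] == sex
        if sel.sum() < 6 or lab.loc[sel, "species"].nunique() != 2:
            logger.info("skipping DFA for sex=%s (insufficient specimens)", sex)
            continue
        dfa = shape_stats.dfa_two_group(
            gpa_res.tangent[sel.to_numpy()],
            lab.loc[sel, "species"].to_numpy(),
            n_perm=config.n_perm_dfa,
            seed=config.seed,
        )
        key = f"dfa_{sex}"
        out[key] = config.out_dir / f"dfa_{sex}.tsv"
        combined = pd.concat(
            {"resubstitution": dfa.resubstitution, "leave_one_out": dfa.loo}
        )
        combined["p_permutation"] = dfa.p_permutation
        combined["mahalanobis"] = dfa.mahalanobis_distance
        _write(combined, out[key])
    return out


def run_molecular(config: RunConfig) -> dict[str, Path]:
    """FASTA -> haplotypes (+ panel match) -> K2P matrix -> NJ/ME tree + bootstrap."""
    if config.fasta_path is None:
        raise ValueError("molecular stage needs fasta_path")
    records = molecular.read_fasta(config.fasta_path)
    if not records:
        raise ValueError(f"no sequences in {config.fasta_path}")
    haps = molecular.collapse_haplotypes(records, mode=config.haplotype_mode)
    if config.panel_path is not None:
        panel = molecular.read_fasta(config.panel_path)
        haps = molecular.match_reference(haps, panel)
    logger.info(
        "molecular: %d sequences -> %d haplotypes, seed=%d, bootstrap_reps=%d",
        haps.n_sequences, len(haps), config.seed, config.bootstrap_reps,
    )
    out = {}
    out["haplotypes"] = config.out_dir / "haplotypes.tsv"
    haps.write_tsv(out["haplotypes"])
    reps = [
        molecular.SequenceRecord(h.haplotype_id, h.sequence, h.species)
        for h in haps.haplotypes
    ]
    matrix = molecular.k2p_matrix(reps)
    out["distances"] = config.out_dir / "k2p_distances.tsv"
    matrix.write_tsv(out["distances"])
    intra = molecular.max_intragroup_distance(matrix, [r.species for r in reps])
    out["intragroup"] = config.out_dir / "max_intragroup_k2p.tsv"
    lines = ["species\tmax_k2p"]
    for sp, v in intra.items():
        lines.append(f"{sp}\t{'NA' if v is None else format(v, '.6g')}")
    out["intragroup"].write_text("\n".join(lines) + "\n")
    if len(reps) >= 4 and config.bootstrap_reps > 0:
        m = min(len(r.sequence) for r in reps)
        trimmed = [
            molecular.SequenceRecord(r.seq_id, r.sequence[:m], r.species) for r in reps
        ]
        tree = molecular.bootstrap_support(
            trimmed, n_reps=config.bootstrap_reps, seed=config.seed
        )
    elif len(reps) >= 3:
        tree = molecular.me_refine(molecular.nj_tree(matrix), matrix)
    else:
        logger.info("fewer than 3 haplotypes; no tree built")
        return out
    out["tree"] = config.out_dir / "haplotypes.nwk"
    molecular.write_newick(tree, out["tree"])
    return out


def run_survey(config: RunConfig) -> dict[str, Path]:
    """Survey TSV -> prevalence/CI, composition, sex ratios, agreement tables."""
    if config.survey_path is None:
        raise ValueError("survey stage needs survey_path")
    table = survey_stats.read_survey_tsv(config.survey_path)
    if table.n_dogs == 0:
        raise ValueError("empty survey table")
    logger.info("survey: %d dogs, %d fleas", table.n_dogs, len(table.fleas))
    out = {}
    k = int(table.dogs["infested"].sum())
    overall = survey_stats.prevalence_ci(k, table.n_dogs, method=config.ci_method)
    rows = [dict(group="all", **overall)]
    prev = pd.DataFrame(rows).set_index("group")
    for grouping in ("age", "sex", "region"):
        sub = survey_stats.infestation_by_group(table, grouping)
        sub.index = [f"{grouping}:{g}" for g in sub.index]
        prev = pd.concat([prev, sub])
    out["prevalence"] = config.out_dir / "prevalence.tsv"
    _write(prev, out["prevalence"])

    counts = table.fleas["species"].value_counts().to_dict()
    comp = survey_stats.species_composition(counts)
    comp_df = pd.DataFrame(
        {"count": pd.Series(counts), "percent": pd.Series(comp)}
    )
    sex_rows = {}
    for sp, grp in table.fleas.groupby("species"):
        f = int((grp["flea_sex"] == "F").sum())
        m = int((grp["flea_sex"] == "M").sum())
        sex_rows[sp] = survey_stats.sex_ratio(f, m) if m >= 1 else np.nan
    comp_df["sex_ratio_f_to_m"] = pd.Series(sex_rows)
    out["composition"] = config.out_dir / "composition.tsv"
    _write(comp_df, out["composition"])

    ctn = table.fleas[table.fleas["cox1_id"].isin(["canis", "orientis"])]
    if len(ctn):
        tab, rates = survey_stats.agreement_table(ctn["cox1_id"], ctn["morphology_id"])
        tab["misclassification_pct"] = rates
        out["agreement"] = config.out_dir / "agreement.tsv"
        _write(tab, out["agreement"])
    return out


def simulate_inputs(out_dir: Path, seed: int = 0) -> dict[str, Path]:
    """Write a full synthetic input set (TPS + labels, FASTA + panel, survey TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    shape_seed, seq_seed, panel_seed, survey_seed, obs_seed = rng.integers(
        0, 2**31 - 1, size=5
    )
    dataset, _ = synthetic.simulate_landmark_dataset(
        synthetic.ShapeSimSpec(seed=int(shape_seed))
    )
    specimens = synthetic.landmark_dataset_to_specimens(dataset)
    paths = {}
    paths["tps"] = out_dir / "landmarks.tps"
    io_tps.write_tps(specimens, paths["tps"])
    labels = dataset.labels.copy()
    truth = (labels["species"] + ":" + labels["sex"]).to_list()
    observed = synthetic.simulate_observer_ids(
        truth, synthetic.ConfusionSpec(seed=int(obs_seed))
    )
    labels["species_morph"] = [o if o == "indeterminate" else o for o in observed]
    paths["labels"] = out_dir / "labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)
    records, _ = synthetic.simulate_cox1_dataset(synthetic.SeqSimSpec(seed=int(seq_seed)))
    paths["fasta"] = out_dir / "cox1.fasta"
    molecular.write_fasta(records, paths["fasta"])
    panel, _ = synthetic.simulate_reference_panel(records, seed=int(panel_seed))
    paths["panel"] = out_dir / "panel.fasta"
    molecular.write_fasta(panel, paths["panel"])
    survey = synthetic.simulate_survey(seed=int(survey_seed))
    paths["survey"] = out_dir / "survey.tsv"
    survey.write_tsv(paths["survey"])
    logger.info("simulated inputs written to %s (seed=%d)", out_dir, seed)
    return paths
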