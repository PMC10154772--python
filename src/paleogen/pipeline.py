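"""End-to-end protocol-comparison experiment.

Builds a synthetic cohort (modern reference populations plus admixed target
individuals), sequences the targets under several library protocols
(undamaged, damaged, UDG-half), calls pseudo-haploid genotypes, and compares
ancestry estimates, F4 statistics and PCA projections between protocol twins
on all SNPs versus transversions only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import yaml

from . import fstats, pca
from .admixture import fit_admixture
from .genotypes import (
    GenotypeMatrix,
    call_pseudohaploid,
    ld_prune,
    mask_transitions,
    to_pseudodiploid,
    trim_terminal,
)
from .simulate import (
    DamageModel,
    apply_damage,
    simulate_frequencies,
    simulate_genotypes,
    simulate_observations,
    simulate_panel,
)

PROTOCOLS = ("undamaged", "damaged", "udg_half")
SNP_SETS = ("all", "transversions_only")


@dataclass
class ExperimentConfig:
    # panel
    n_snps: int = 12000
    transition_fraction: float = 0.8
    polarize_transitions: bool = True
    # population model
    n_pops: int = 2
    fst_per_pop: tuple = (0.12, 0.18)
    n_modern_per_pop: int = 25
    n_targets: int = 1
    target_admixture: str = "even"  # "even" | "dirichlet"
    # sequencing
    coverage: float = 2.0
    fragment_length_mean: float = 65.0
    # damage
    d_max5: float = 0.3
    d_max3: float = 0.3
    decay: float = 0.7
    damage_mode: str = "double_strand"
    protocols: tuple = PROTOCOLS
    # calling / filtering
    min_bq: int = 30
    trim_bp: int = 2
    snp_sets: tuple = SNP_SETS
    prune: bool = False
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    # model fitting
    K_fit: int | None = None  # defaults to n_pops + 1
    haploid_mode: str = "single"  # pseudo-haploid rows as one Bernoulli trial
    n_starts: int = 3
    tol: float = 1e-4
    max_iter: int = 500
    block_size: int = 100
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.protocols) < 2:
            raise ValueError("need at least two protocols to compare")
        unknown = set(self.protocols) - set(PROTOCOLS)
        if unknown:
            raise ValueError(f"unknown protocols: {sorted(unknown)}")
        if "undamaged" not in self.protocols:
            raise ValueError("the undamaged protocol is the comparison baseline")

    @property
    def k_fit(self) -> int:
        return self.K_fit if self.K_fit is not None else self.n_pops + 1

    def damage_model(self, udg_half: bool) -> DamageModel:
        return DamageModel(
            d_max5=self.d_max5,
            d_max3=self.d_max3,
            decay=self.decay,
            mode=self.damage_mode,
            udg_half=udg_half,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fst_per_pop", "protocols", "snp_sets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DistortionReport:
    config: dict
    seeds: dict
    sets: dict
    accounting: dict

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "sets": self.sets,
            "accounting": self.accounting,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def snp_set_accounting(nonmissing: dict, panel) -> dict:
    """SNP-set overlap bookkeeping across call sets.

    ``nonmissing`` maps library name to a boolean non-missing mask over the
    shared panel.  Returns per-library counts and all pairwise/higher-order
    intersection counts, for all SNPs and for transversions only.
    """
    if len(nonmissing) < 2:
        raise ValueError("need at least 2 call sets")
    tv = panel.is_transversion
    out = {}
    for set_name, keep in (("all", np.ones(len(panel), bool)), ("transversions_only", tv)):
        masks = {name: m & keep for name, m in nonmissing.items()}
        entry = {"per_library": {k: int(v.sum()) for k, v in masks.items()}}
        inter = {}
        names = sorted(masks)
        for r in range(2, len(names) + 1):
            for combo in combinations(names, r):
                acc = np.ones(len(panel), bool)
                for name in combo:
                    acc &= masks[name]
                inter["&".join(combo)] = int(acc.sum())
        entry["intersections"] = inter
        out[set_name] = entry
    return out


def _protocol_matrices(cfg: ExperimentConfig, panel, targets, seeds) -> dict:
    """Sequence the target individuals under each protocol and call
    pseudo-haploid genotypes; damage and calling seeds are shared across
    protocols so protocol copies are paired replicates of the same reads."""
    obs_base = simulate_observations(
        targets, panel, cfg.coverage, cfg.fragment_length_mean,
        seed=seeds["observations"],
    )
    out = {}
    for protocol in cfg.protocols:
        if protocol == "undamaged":
            obs = obs_base
        elif protocol == "damaged":
            obs = apply_damage(
                obs_base, panel, cfg.damage_model(udg_half=False), seed=seeds["damage"]
            )
        else:  # udg_half
            obs = apply_damage(
                obs_base, panel, cfg.damage_model(udg_half=True), seed=seeds["damage"]
            )
            obs = trim_terminal(obs, cfg.trim_bp)
        calls = call_pseudohaploid(
            obs, panel, min_bq=cfg.min_bq, seed=seeds["calling"],
            samples=targets.samples,
        )
        Gp = to_pseudodiploid(calls)
        Gp.samples = [f"{s}__{protocol}" for s in Gp.samples]
        out[protocol] = Gp
    return out


def _haploid_freq(G: GenotypeMatrix, sample_id) -> np.ndarray:
    """Per-SNP 0/1 allele state of one pseudo-haploid sample, NaN missing."""
    row = G.counts[G.sample_index(sample_id)].astype(float)
    row[row < 0] = np.nan
    return row / 2.0


def run_experiment(cfg: ExperimentConfig) -> DistortionReport:
    ss = np.random.SeedSequence(cfg.seed)
    names = ["panel", "frequencies", "target_q", "modern", "targets",
             "observations", "damage", "calling", "admixture", "prune"]
    seeds = {n: int(s.generate_state(1)[0]) % (2**31)
             for n, s in zip(names, ss.spawn(len(names)))}

    panel = simulate_panel(
        cfg.n_snps, cfg.transition_fraction, seed=seeds["panel"],
        polarize_transitions=cfg.polarize_transitions,
    )
    model = simulate_frequencies(
        panel, cfg.n_pops, cfg.fst_per_pop, seed=seeds["frequencies"]
    )

    q_modern = np.repeat(np.eye(cfg.n_pops), cfg.n_modern_per_pop, axis=0)
    modern_ids = [
        f"pop{k}_ind{i}"
        for k in range(cfg.n_pops)
        for i in range(cfg.n_modern_per_pop)
    ]
    modern = simulate_genotypes(model, q_modern, seed=seeds["modern"],
                                sample_ids=modern_ids)
    modern_pops = {
        f"pop{k}": [f"pop{k}_ind{i}" for i in range(cfg.n_modern_per_pop)]
        for k in range(cfg.n_pops)
    }

    if cfg.target_admixture == "even":
        q_targets = np.full((cfg.n_targets, cfg.n_pops), 1.0 / cfg.n_pops)
    elif cfg.target_admixture == "dirichlet":
        rng_q = np.random.default_rng(seeds["target_q"])
        q_targets = rng_q.dirichlet(np.ones(cfg.n_pops), size=cfg.n_targets)
    else:
        raise ValueError(f"unknown target_admixture {cfg.target_admixture!r}")
    target_ids = [f"target_{t}" for t in range(cfg.n_targets)]
    targets = simulate_genotypes(model, q_targets, seed=seeds["targets"],
                                 sample_ids=target_ids)

    protocol_mats = _protocol_matrices(cfg, panel, targets, seeds)
    nonmissing = {
        p: ~m.missing_mask.all(axis=0) if m.n_samples > 1 else ~m.missing_mask[0]
        for p, m in protocol_mats.items()
    }
    accounting = snp_set_accounting(nonmissing, panel)

    combined = GenotypeMatrix.concatenate([modern] + list(protocol_mats.values()))

    sets: dict = {}
    for set_name in cfg.snp_sets:
        if set_name == "all":
            sub = combined
        elif set_name == "transversions_only":
            sub = mask_transitions(combined)
        else:
            raise ValueError(f"unknown SNP set {set_name!r}")
        n_after_mask = sub.n_snps
        if cfg.prune:
            kept = ld_prune(sub, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
            sub = sub.subset_snps(kept)
        entry: dict = {
            "n_snps": sub.n_snps,
            "n_after_mask": n_after_mask,
        }

        # ancestry estimation on moderns + all protocol copies
        fit = fit_admixture(
            sub, cfg.k_fit, n_starts=cfg.n_starts, tol=cfg.tol,
            max_iter=cfg.max_iter, seed=seeds["admixture"],
            haploid_mode=cfg.haploid_mode, init_q="uniform",
        )
        sample_index = {s: i for i, s in enumerate(sub.samples)}
        q_of = lambda s: fit.Q[sample_index[s]]
        divergence = {}
        for protocol in cfg.protocols:
            if protocol == "undamaged":
                continue
            per_target = [
                float(np.abs(
                    q_of(f"{t}__{protocol}") - q_of(f"{t}__undamaged")
                ).mean())
                for t in target_ids
            ]
            divergence[protocol] = per_target
        entry["admixture_divergence"] = divergence
        entry["admixture_loglik"] = fit.loglik

        # protocol-vs-component correlation over all protocol copies
        copy_ids = [f"{t}__{p}" for p in cfg.protocols for t in target_ids]
        indicator = np.array(
            [0.0 if s.endswith("__damaged") else 1.0 for s in copy_ids]
        )
        Qc = np.vstack([q_of(s) for s in copy_ids])
        if len(set(indicator)) == 2:
            mean_dam = Qc[indicator == 0].mean(axis=0)
            mean_ok = Qc[indicator == 1].mean(axis=0)
            comp = int(np.argmax(mean_dam - mean_ok))
            qv = Qc[:, comp]
            if qv.std() > 0 and indicator.std() > 0:
                corr = float(np.corrcoef(indicator, qv)[0, 1])
            else:
                corr = float("nan")
            entry["damage_component"] = comp
            entry["protocol_component_correlation"] = corr

        # F4 statistics against modern frequencies and a fixed outgroup
        w_freq, _ = fstats.allele_frequencies(sub, modern_pops["pop0"])
        x_pop = "pop1" if cfg.n_pops > 1 else "pop0"
        x_freq, _ = fstats.allele_frequencies(sub, modern_pops[x_pop])
        o_freq = np.zeros(sub.n_snps)
        # keep a sensible number of jackknife blocks on small SNP sets
        block = max(1, min(cfg.block_size, sub.n_snps // 20))
        f4_entry: dict = {}
        for protocol in cfg.protocols:
            y = _haploid_freq(sub, f"{target_ids[0]}__{protocol}")
            res = fstats.f4(w_freq, y, x_freq, o_freq, block)
            f4_entry[protocol] = {
                "estimate": res.estimate, "stderr": res.stderr,
                "z": res.z, "n_snps": res.n_snps, "n_blocks": res.n_blocks,
            }
            if protocol != "undamaged":
                y0 = _haploid_freq(sub, f"{target_ids[0]}__undamaged")
                con = fstats.f4_paired_contrast(
                    w_freq, y, y0, x_freq, o_freq, block
                )
                f4_entry[f"{protocol}_vs_undamaged"] = {
                    "estimate": con.estimate, "stderr": con.stderr,
                    "z": con.z, "n_snps": con.n_snps, "n_blocks": con.n_blocks,
                }
        entry["f4"] = f4_entry

        # PCA projection of protocol copies onto the modern reference
        X_ref = pca.encode_genotypes(sub.subset_samples(modern.samples))
        pmodel = pca.fit_reference(X_ref, cfg.pca_components)
        scores = {}
        for s in copy_ids:
            row = pca.encode_genotypes(sub.subset_samples([s]))[0]
            scores[s] = pca.project(pmodel, row)
        entry["pca_scores"] = {k: v.tolist() for k, v in scores.items()}
        copies_t0 = [f"{target_ids[0]}__{p}" for p in cfg.protocols]
        entry["pca_group_spread"] = float(np.mean([
            np.linalg.norm(scores[a] - scores[b])
            for a, b in combinations(copies_t0, 2)
        ]))
        entry["pca_twin_distance"] = {
            protocol: [
                float(np.linalg.norm(
                    scores[f"{t}__{protocol}"] - scores[f"{t}__undamaged"]
                ))
                for t in target_ids
            ]
            for protocol in cfg.protocols if protocol != "undamaged"
        }

        # group concordance among protocol copies of the first target
        groups = []
        for protocol in cfg.protocols:
            f, n_al = fstats.allele_frequencies(
                sub, [f"{target_ids[0]}__{protocol}"]
            )
            groups.append((f, n_al))
        try:
            entry["group_fst"] = fstats.hudson_fst_groups(groups)
        except ValueError:
            entry["group_fst"] = float("nan")

        sets[set_name] = entry

    return DistortionReport(
        config=cfg.to_dict(), seeds=seeds, sets=sets, accounting=accounting
    )


def write_report(report: DistortionReport, out_dir: str) -> None:
    """Persist report.json plus TSV side-tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    report.to_json(os.path.join(out_dir, "report.json"))
    rows = []
    for set_name, entry in report.sets.items():
        for protocol, stats in entry["f4"].items():
            rows.append(
                {"snp_set": set_name, "comparison": protocol, **stats}
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "f4.tsv"), sep="\t", index=False
    )
    score_rows = []
    for set_name, entry in report.sets.items():
        for sample, sc in entry["pca_scores"].items():
            score_rows.append(
                {"snp_set": set_name, "sample": sample,
                 **{f"PC{i + 1}": v for i, v in enumerate(sc)}}
            )
    pd.DataFrame(score_rows).to_csv(
        os.path.join(out_dir, "pca_scores.tsv"), sep="\t", index=False
    )
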