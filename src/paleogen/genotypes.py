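"""Genotype-matrix handling: pseudo-haploid calling, terminal trimming,
transition masking, LD pruning and EIGENSTRAT I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .simulate import ObservationSet, SNPPanel

MISSING = -1  # internal missing code; EIGENSTRAT uses the character '9'


class EigenstratFormatError(ValueError):
    """Raised when .geno/.snp/.ind files are mutually inconsistent."""


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix, samples x SNPs.

    ``counts`` holds 0/1/2 with ``-1`` for missing.  Pseudo-haploid samples
    may only carry {0, 2, missing}.
    """

    samples: list
    panel: "SNPPanel"
    counts: np.ndarray
    ploidy: np.ndarray  # per-sample: "diploid" | "pseudo_haploid"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=object)
        n, m = self.counts.shape
        if len(self.samples) != n:
            raise ValueError("sample list and count matrix disagree")
        if len(self.panel) != m:
            raise ValueError("panel and count matrix disagree")
        if len(self.ploidy) != n:
            raise ValueError("ploidy flags and sample list disagree")
        bad = ~np.isin(self.counts, [MISSING, 0, 1, 2])
        if np.any(bad):
            raise ValueError("genotype counts must be in {0, 1, 2, missing}")
        ph = self.ploidy == "pseudo_haploid"
        if np.any(ph) and np.any(self.counts[ph] == 1):
            raise ValueError("pseudo-haploid samples cannot carry heterozygotes")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def sample_index(self, sample_id) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            panel=self.panel.subset(index),
            counts=self.counts[:, index],
            ploidy=self.ploidy.copy(),
        )

    def subset_samples(self, sample_ids: Sequence) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            panel=self.panel,
            counts=self.counts[idx],
            ploidy=self.ploidy[idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack sample sets sharing one panel."""
        first = parts[0]
        for p in parts[1:]:
            if len(p.panel) != len(first.panel) or np.any(
                p.panel.snp_id != first.panel.snp_id
            ):
                raise ValueError("cannot concatenate matrices on different panels")
        return GenotypeMatrix(
            samples=[s for p in parts for s in p.samples],
            panel=first.panel,
            counts=np.vstack([p.counts for p in parts]),
            ploidy=np.concatenate([p.ploidy for p in parts]),
        )


@dataclass
class HaploidCallSet:
    """One called allele per (sample, SNP): 0=ref, 1=alt, -1=missing."""

    samples: list
    panel: "SNPPanel"
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.panel)):
            raise ValueError("call matrix shape inconsistent with samples/panel")
        if np.any(~np.isin(self.calls, [-1, 0, 1])):
            raise ValueError("calls must be 0 (ref), 1 (alt) or -1 (missing)")


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer; maps uint64 to well-mixed uint64."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def trim_terminal(obs: "ObservationSet", n_bp: int = 2) -> "ObservationSet":
    """Drop observations within ``n_bp`` of either fragment end."""
    if n_bp < 0:
        raise ValueError("n_bp must be >= 0")
    if n_bp == 0:
        return obs
    f = obs.frame
    keep = np.minimum(np.asarray(f["dist5"]), np.asarray(f["dist3"])) > n_bp
    return obs.with_frame(f.loc[keep])


def call_pseudohaploid(
    obs: "ObservationSet",
    panel: "SNPPanel",
    min_bq: int = 30,
    seed: int | None = None,
    samples: Sequence | None = None,
) -> HaploidCallSet:
    """Random pseudo-haploid calling.

    Observations below ``min_bq`` or carrying a base outside the SNP's allele
    pair are discarded; among the survivors of each (sample, SNP) cell one is
    chosen uniformly at random and its allele reported.  Each record receives
    a pseudorandom key derived from the seed and the record's content (cell,
    base, quality, fragment geometry, duplicate rank) and the cell's maximum
    key wins, so calls do not depend on the input row order and two
    observation sets differing at a few records yield identical calls at
    every unaffected cell.
    """
    from .simulate import BASES, base_codes

    f = obs.frame
    snp_idx = np.asarray(f["snp_index"], dtype=np.int64)
    codes = base_codes(f["base"])
    bq = np.asarray(f["base_quality"])
    ref_codes = np.searchsorted(BASES, panel.ref).astype(np.int8)
    alt_codes = np.searchsorted(BASES, panel.alt).astype(np.int8)
    ok = (bq >= min_bq) & (
        (codes == ref_codes[snp_idx]) | (codes == alt_codes[snp_idx])
    )

    sid = f["sample_id"]
    if isinstance(sid.dtype, pd.CategoricalDtype):
        raw_code = sid.cat.codes.to_numpy().astype(np.int64)
        raw_cats = [str(c) for c in sid.cat.categories]
    else:
        cat = pd.Categorical(np.asarray(sid, dtype=object))
        raw_code = cat.codes.astype(np.int64)
        raw_cats = [str(c) for c in cat.categories]
    if samples is None:
        present = np.unique(raw_code[ok])
        samples = sorted(raw_cats[i] for i in present if i >= 0)
    samples = list(samples)
    pos = {str(s): i for i, s in enumerate(samples)}
    remap = np.array([pos.get(c, -1) for c in raw_cats], dtype=np.int64)
    sample_code = remap[raw_code]
    ok &= sample_code >= 0

    snp_ok = snp_idx[ok]
    base_ok = codes[ok].astype(np.uint64)
    cell = sample_code[ok] * len(panel) + snp_ok
    bq_ok = bq[ok].astype(np.uint64)
    fl_ok = np.asarray(f["fragment_length"])[ok].astype(np.uint64)
    d5_ok = np.asarray(f["dist5"])[ok].astype(np.uint64)

    # canonical order: cell, then full record content
    order = np.lexsort((d5_ok, fl_ok, bq_ok, base_ok, cell))
    cell = cell[order]
    base_sorted = base_ok[order].astype(np.int8)
    content = (
        cell.astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15)
        + base_ok[order] * np.uint64(0xBF58476D1CE4E5B9)
        + bq_ok[order] * np.uint64(0x94D049BB133111EB)
        + fl_ok[order] * np.uint64(0xD6E8FEB86659FD93)
        + d5_ok[order] * np.uint64(0xA0761D6478BD642F)
    )
    # rank duplicates of identical content within a cell so every record
    # gets an independent key
    dup = np.zeros(len(content), dtype=np.uint64)
    if len(content) > 1:
        idx = np.arange(len(content))
        boundary = np.ones(len(content), dtype=bool)
        boundary[1:] = content[1:] != content[:-1]
        run_start = np.maximum.accumulate(np.where(boundary, idx, 0))
        dup = (idx - run_start).astype(np.uint64)
    key = _splitmix64(
        content + dup * np.uint64(0xE7037ED1A0B428DB)
        + np.uint64(np.random.default_rng(seed).integers(0, 2**63))
    )

    # winner per cell: record with the maximal key
    win_order = np.lexsort((key, cell))
    last = np.ones(len(cell), dtype=bool)
    last[:-1] = cell[win_order][1:] != cell[win_order][:-1]
    winners = win_order[last]
    chosen_cells = cell[winners]
    chosen_bases = base_sorted[winners]

    calls = np.full((len(samples), len(panel)), MISSING, dtype=np.int8)
    si = chosen_cells // len(panel)
    sj = chosen_cells % len(panel)
    calls[si, sj] = (chosen_bases == alt_codes[sj]).astype(np.int8)
    return HaploidCallSet(samples=samples, panel=panel, calls=calls)


def to_pseudodiploid(calls: HaploidCallSet) -> GenotypeMatrix:
    """Code haploid calls as homozygotes: ref -> 0, alt -> 2."""
    counts = np.where(calls.calls == 1, 2, calls.calls).astype(np.int8)
    return GenotypeMatrix(
        samples=list(calls.samples),
        panel=calls.panel,
        counts=counts,
        ploidy=np.array(["pseudo_haploid"] * len(calls.samples), dtype=object),
    )


def mask_transitions(G: GenotypeMatrix) -> GenotypeMatrix:
    """Restrict to transversion-class SNPs (drop {C,T} and {A,G} pairs)."""
    keep = G.panel.is_transversion
    if not np.any(keep):
        raise ValueError("no transversion SNPs remain after masking")
    return G.subset_snps(np.flatnonzero(keep))


def _pairwise_complete_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns, missing (NaN) entries
    excluded pairwise."""
    valid = ~np.isnan(X)
    Xz = np.where(valid, X, 0.0)
    v = valid.astype(float)
    n = v.T @ v
    s = Xz.T @ v
    ss = (Xz * Xz).T @ v
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s * s.T / n
        var_i = ss - s**2 / n
        var_j = ss.T - (s.T) ** 2 / n
        r2 = cov**2 / (var_i * var_j)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Sliding-window LD pruning on genotype counts.

    Within each window the later SNP of any pair whose squared Pearson
    correlation exceeds ``r2_max`` is removed (greedy, keep-first); the
    window advances by ``step``.  Returns the retained SNP indices.
    """
    if window < step:
        raise ValueError("window must be >= step")
    m = G.n_snps
    X = G.counts.astype(float)
    X[G.counts == MISSING] = np.nan
    removed = np.zeros(m, dtype=bool)
    start = 0
    while start < m:
        idx = np.arange(start, min(start + window, m))
        active = idx[~removed[idx]]
        if len(active) > 1:
            r2 = _pairwise_complete_r2(X[:, active])
            alive = np.ones(len(active), dtype=bool)
            for i in range(len(active)):
                if not alive[i]:
                    continue
                hits = np.flatnonzero((r2[i] > r2_max) & alive)
                hits = hits[hits > i]
                alive[hits] = False
            removed[active[~alive]] = True
        if start + window >= m:
            break
        start += step
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# EIGENSTRAT + observation TSV I/O

def write_eigenstrat(
    G: GenotypeMatrix,
    prefix: str,
    populations: Sequence | None = None,
) -> None:
    """Write ``prefix``.geno/.snp/.ind (geno: one row per SNP, one character
    per sample, 9 = missing)."""
    panel = G.panel
    with open(f"{prefix}.snp", "w") as fh:
        for i in range(len(panel)):
            fh.write(
                f"{panel.snp_id[i]}\t{panel.chromosome[i]}\t0.0\t"
                f"{panel.position[i]}\t{panel.ref[i]}\t{panel.alt[i]}\n"
            )
    if populations is None:
        populations = ["pop"] * G.n_samples
    with open(f"{prefix}.ind", "w") as fh:
        for s, pop in zip(G.samples, populations):
            fh.write(f"{s}\tU\t{pop}\n")
    geno = G.counts.T.copy()
    geno[geno == MISSING] = 9
    digits = np.array(["0", "1", "2", "", "", "", "", "", "", "9"])
    with open(f"{prefix}.geno", "w") as fh:
        for row in geno:
            fh.write("".join(digits[row]) + "\n")


def read_eigenstrat(prefix: str, ploidy: str | Sequence = "diploid") -> GenotypeMatrix:
    """Read ``prefix``.geno/.snp/.ind back into a :class:`GenotypeMatrix`."""
    from .simulate import SNPPanel  # deferred: avoids import cycle

    snp = pd.read_csv(
        f"{prefix}.snp",
        sep=r"\s+",
        header=None,
        names=["snp_id", "chromosome", "gpos", "position", "ref", "alt"],
        dtype={"snp_id": str, "ref": str, "alt": str},
    )
    panel = SNPPanel(
        snp_id=snp["snp_id"].to_numpy(dtype=object),
        chromosome=snp["chromosome"].to_numpy(),
        position=snp["position"].to_numpy(),
        ref=snp["ref"].to_numpy(dtype="U1"),
        alt=snp["alt"].to_numpy(dtype="U1"),
    )
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", header=None, names=["sample", "sex", "pop"],
        dtype=str,
    )
    samples = list(ind["sample"])
    with open(f"{prefix}.geno") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if len(lines) != len(panel):
        raise EigenstratFormatError(
            f".geno has {len(lines)} rows but .snp lists {len(panel)} SNPs"
        )
    n = len(samples)
    counts = np.empty((n, len(panel)), dtype=np.int8)
    for j, line in enumerate(lines):
        if len(line) != n:
            raise EigenstratFormatError(
                f".geno row {j} has {len(line)} columns but .ind lists {n} samples"
            )
        row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
        counts[:, j] = row
    counts[counts == 9] = MISSING
    if isinstance(ploidy, str):
        ploidy_arr = np.array([ploidy] * n, dtype=object)
    else:
        ploidy_arr = np.asarray(ploidy, dtype=object)
    return GenotypeMatrix(samples=samples, panel=panel, counts=counts,
                          ploidy=ploidy_arr)


def write_observations(obs: "ObservationSet", panel: "SNPPanel", path: str) -> None:
    """Write observations as TSV with snp ids resolved from the panel."""
    f = obs.frame
    out = pd.DataFrame(
        {
            "snp_id": panel.snp_id[np.asarray(f["snp_index"])],
            "sample": f["sample_id"].to_numpy(),
            "base": f["base"].to_numpy(),
            "bq": f["base_quality"].to_numpy(),
            "fraglen": f["fragment_length"].to_numpy(),
            "dist5": f["dist5"].to_numpy(),
            "dist3": f["dist3"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_observations(path: str, panel: "SNPPanel") -> "ObservationSet":
    from .simulate import ObservationSet  # deferred: avoids import cycle

    raw = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample": str})
    lookup = pd.Series(np.arange(len(panel)), index=panel.snp_id.astype(str))
    frame = pd.DataFrame(
        {
            "snp_index": lookup.loc[raw["snp_id"]].to_numpy(dtype=np.int64),
            "sample_id": raw["sample"].to_numpy(dtype=object),
            "base": raw["base"].to_numpy(dtype="U1"),
            "base_quality": raw["bq"].to_numpy(),
            "fragment_length": raw["fraglen"].to_numpy(),
            "dist5": raw["dist5"].to_numpy(),
            "dist3": raw["dist3"].to_numpy(),
        }
    )
    return ObservationSet(frame)
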