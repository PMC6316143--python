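"""Multispecies-coalescent simulation on the fixed great-ape species tree.

Species tree topology is (((Homo, Pan), Gorilla), Pongo), with one haploid
sequence sampled per species.  Speciation times (tau) and population-mutation
parameters (theta = 4*Ne*mu) are in expected substitutions/site, so gene
genealogies and branch lengths come out in s/s and the mutation rate never
appears explicitly: within an ancestral population holding k lineages the
next coalescence waits Exp(rate = k(k-1)/theta), i.e. a pair coalesces after
a mean theta/2.

The simulator is the data-generating half of the pipeline: it produces
per-locus FASTA alignments plus a manifest recording the true parameters and
every realized genealogy, so downstream estimates can be checked against
truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substitution import BASES, SubstitutionModel, jc69_mismatch_probability

TAXA = ("Homo", "Pan", "Gorilla", "Pongo")


@dataclass(frozen=True)
class SpeciesTreeParams:
    """Speciation times and ancestral-population theta on (((H,C),G),O).

    All values in substitutions/site.  Tip populations hold a single sampled
    lineage each, so no within-species coalescence occurs and tip theta is
    irrelevant (fixed at 0).  Defaults put the mean Homo-Pan coalescent
    height at tau_hc + theta_hc/2 = 0.00625 s/s, the Homo-Gorilla mean at
    0.008 and the Homo-Pongo mean at 0.013 s/s.
    """

    tau_hc: float = 0.00473
    tau_hcg: float = 0.0074
    tau_root: float = 0.0122
    theta_hc: float = 0.00304
    theta_hcg: float = 0.0012
    theta_root: float = 0.0016

    def __post_init__(self) -> None:
        taus = (self.tau_hc, self.tau_hcg, self.tau_root)
        thetas = (self.theta_hc, self.theta_hcg, self.theta_root)
        if not all(np.isfinite(taus)) or not all(np.isfinite(thetas)):
            raise ValueError("tau and theta must be finite")
        if not 0 < self.tau_hc < self.tau_hcg < self.tau_root:
            raise ValueError("need 0 < tau_hc < tau_hcg < tau_root")
        if any(t < 0 for t in thetas):
            raise ValueError("theta must be non-negative")


@dataclass
class GeneGenealogy:
    """One realized gene tree for a locus, heights in substitutions/site."""

    locus_id: str
    newick: str
    t_hc: float            # height of the MRCA of Homo and Pan
    t_hcg: float           # height of the MRCA of Homo, Pan, Gorilla
    t_root: float          # height of the root (all four taxa)
    hc_sister: bool        # True if Homo and Pan are sisters in the gene tree
    coalescences: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class LocusAlignment:
    """A gap-free multi-taxon alignment; rows follow ``taxa`` order.

    ``codes`` holds base indices into "ACGT" with shape (n_taxa, length).
    """

    locus_id: str
    taxa: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, length)")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 3):
            raise ValueError("codes must index ACGT")

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(BASES[c] for c in row)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(t)), id=t, description="")
            for t in self.taxa
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, locus_id: str | None = None) -> "LocusAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in {path}")
        lookup = {b: i for i, b in enumerate(BASES)}
        codes = np.empty((len(records), lengths.pop()), dtype=np.int8)
        for i, rec in enumerate(records):
            seq = str(rec.seq).upper()
            try:
                codes[i] = [lookup[b] for b in seq]
            except KeyError as exc:
                raise ValueError(f"non-ACGT base in {path}: {exc}") from exc
        return cls(
            locus_id=locus_id or Path(path).stem,
            taxa=tuple(r.id for r in records),
            codes=codes,
        )


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

@dataclass
class _Lineage:
    tips: frozenset[str]
    height: float
    newick: str


def _coalesce_epoch(
    lineages: list[_Lineage],
    theta: float,
    start: float,
    end: float,
    rng: np.random.Generator,
    events: list[tuple[frozenset[str], float]],
) -> list[_Lineage]:
    """Run the Kingman coalescent in one population over [start, end)."""
    t = start
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        if theta > 0:
            wait = rng.exponential(theta / (k * (k - 1)))
        else:
            wait = 0.0  # zero-variance limit: instantaneous coalescence
        if t + wait >= end:
            break
        t += wait
        i, j = sorted(int(v) for v in rng.choice(k, size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        merged = _Lineage(
            tips=left.tips | right.tips,
            height=t,
            newick="({}:{:.10g},{}:{:.10g})".format(
                left.newick, t - left.height, right.newick, t - right.height
            ),
        )
        events.append((merged.tips, t))
        lineages.append(merged)
    return lineages


def simulate_genealogy(
    params: SpeciesTreeParams,
    rng: np.random.Generator | int,
    locus_id: str = "locus",
) -> GeneGenealogy:
    """Sample one gene genealogy under the MSC on the great-ape species tree.

    Lineages that fail to coalesce within an ancestral population carry into
    the parent population, so incomplete lineage sorting (Homo and Pan not
    sisters in the gene tree) arises naturally in the HCG ancestor and above.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tips = {name: _Lineage(frozenset({name}), 0.0, name) for name in TAXA}
    events: list[tuple[frozenset[str], float]] = []

    hc = _coalesce_epoch(
        [tips["Homo"], tips["Pan"]], params.theta_hc,
        params.tau_hc, params.tau_hcg, rng, events,
    )
    hcg = _coalesce_epoch(
        hc + [tips["Gorilla"]], params.theta_hcg,
        params.tau_hcg, params.tau_root, rng, events,
    )
    root = _coalesce_epoch(
        hcg + [tips["Pongo"]], params.theta_root,
        params.tau_root, np.inf, rng, events,
    )
    (tree,) = root

    def mrca(*names: str) -> float:
        want = frozenset(names)
        return min(h for tips_, h in events if want <= tips_)

    return GeneGenealogy(
        locus_id=locus_id,
        newick=tree.newick + ";",
        t_hc=mrca("Homo", "Pan"),
        t_hcg=mrca("Homo", "Pan", "Gorilla"),
        t_root=tree.height,
        hc_sister=any(t == frozenset({"Homo", "Pan"}) for t, _ in events),
        coalescences=[(",".join(sorted(t)), h) for t, h in events],
    )


def simulate_pair_heights(
    tau: float, theta: float, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Coalescence heights of a two-lineage MSC: tau + Exp(mean theta/2).

    This is the pairwise reduction used throughout: the Homo-Pan gene
    divergence at a locus is the speciation time plus the exponential
    coalescent waiting time in the ancestral population, so the mean height
    is tau + theta/2 (d_T/2 on the distance scale).
    """
    if not (np.isfinite(tau) and np.isfinite(theta)) or tau < 0 or theta < 0:
        raise ValueError("tau and theta must be finite and non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return tau + rng.exponential(theta / 2.0, size=n)


def simulate_pair_counts(
    tau: float,
    theta: float,
    n_loci: int,
    length: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus JC69 difference counts for a two-lineage MSC sample.

    Returns (x, L, heights): x differing sites out of L at each locus, with
    per-site mismatch probability equal to the JC69 value at distance
    2 * height.  This is the sufficient-statistic form the Bayesian
    inference consumes, bypassing full sequence simulation.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    heights = simulate_pair_heights(tau, theta, n_loci, rng)
    p = jc69_mismatch_probability(2.0 * heights)
    x = rng.binomial(length, p)
    lengths = np.full(n_loci, length, dtype=np.int64)
    return x.astype(np.int64), lengths, heights


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def simulate_alignment(
    genealogy: GeneGenealogy,
    model: SubstitutionModel,
    length: int,
    rng: np.random.Generator | int,
) -> LocusAlignment:
    """Evolve a gap-free alignment of given length down the genealogy.

    Sites are independent; each draws a rate from the model's
    discrete-gamma/invariant mixture, and states propagate tip-ward with the
    model's transition matrices at (branch length x site rate).
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rates, weights = model.site_rate_mixture()
    cats = rng.choice(len(rates), size=length, p=weights)
    root_states = rng.choice(4, size=length, p=np.asarray(model.base_freqs))

    tree = _tree_from_newick(genealogy.newick)
    seqs: dict[str, np.ndarray] = {}

    def descend(node: dict, states: np.ndarray) -> None:
        if not node["children"]:
            seqs[node["name"]] = states
            return
        for child, branch in node["children"]:
            child_states = states.copy()
            for c in range(len(rates)):
                t = branch * rates[c]
                if t == 0:
                    continue
                mask = cats == c
                if not mask.any():
                    continue
                cum = np.cumsum(model.transition_matrix(t), axis=1)
                u = rng.random(int(mask.sum()))
                child_states[mask] = (u[:, None] > cum[states[mask]]).sum(axis=1)
            descend(child, child_states)

    descend(tree, root_states)
    codes = np.stack([seqs[t] for t in TAXA]).astype(np.int8)
    return LocusAlignment(locus_id=genealogy.locus_id, taxa=TAXA, codes=codes)


def _tree_from_newick(newick: str) -> dict:
    """Parse the simulator's own newick output into nested dicts."""
    s = newick.rstrip(";")

    def parse(fragment: str) -> dict:
        if not fragment.startswith("("):
            return {"name": fragment, "children": []}
        depth = 0
        parts = []
        last = 1
        for i, ch in enumerate(fragment):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch == "," and depth == 1:
                parts.append(fragment[last:i])
                last = i + 1
        parts.append(fragment[last : len(fragment) - 1])
        children = []
        for part in parts:
            depth2 = 0
            for j in range(len(part) - 1, -1, -1):
                ch = part[j]
                if ch == ")":
                    depth2 += 1
                elif ch == "(":
                    depth2 -= 1
                elif ch == ":" and depth2 == 0:
                    sub, br = part[:j], float(part[j + 1 :])
                    break
            else:
                raise ValueError(f"missing branch length in {part!r}")
            children.append((parse(sub), br))
        return {"name": None, "children": children}

    return parse(s)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def locus_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-locus substream: reproducible locus by locus."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_dataset(
    params: SpeciesTreeParams,
    model: SubstitutionModel,
    n_loci: int,
    length: int,
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Simulate ``n_loci`` FASTA alignments plus a ground-truth manifest.

    Fully reproducible from (seed, params, model): each locus uses its own
    RNG substream derived from the dataset seed and locus index, so any
    locus can be regenerated without the others.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci = []
    for i in range(n_loci):
        rng = locus_rng(seed, i)
        locus_id = f"locus_{i:06d}"
        gen = simulate_genealogy(params, rng, locus_id=locus_id)
        aln = simulate_alignment(gen, model, length, rng)
        aln.to_fasta(out / f"{locus_id}.fasta")
        loci.append(
            {
                "locus_id": locus_id,
                "newick": gen.newick,
                "t_hc": gen.t_hc,
                "t_hcg": gen.t_hcg,
                "t_root": gen.t_root,
                "hc_sister": gen.hc_sister,
            }
        )
    manifest = {
        "seed": seed,
        "n_loci": n_loci,
        "length": length,
        "total_sites": n_loci * length,
        "params": asdict(params),
        "model": {
            "name": model.name,
            "base_freqs": list(model.base_freqs),
            "gamma_shape": model.gamma_shape,
            "p_inv": model.p_inv,
        },
        "taxa": list(TAXA),
        "loci": loci,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_loci(directory: str | Path) -> list[LocusAlignment]:
    """Load every ``*.fasta`` locus in a directory, sorted by file name."""
    paths = sorted(Path(directory).glob("*.fasta"))
    if not paths:
        raise ValueError(f"no FASTA loci found in {directory}")
    return [LocusAlignment.from_fasta(p) for p in paths]


def concatenate(loci: list[LocusAlignment]) -> LocusAlignment:
    """Concatenate loci into a single supermatrix alignment."""
    if not loci:
        raise ValueError("no loci to concatenate")
    taxa = loci[0].taxa
    for aln in loci:
        if aln.taxa != taxa:
            raise ValueError("loci must share the same taxon set and order")
    codes = np.concatenate([a.codes for a in loci], axis=1)
    return LocusAlignment(locus_id="supermatrix", taxa=taxa, codes=codes)
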