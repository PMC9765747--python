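"""Synthetic gut-community generator with a ground-truth ledger.

The generator emulates the statistical structure of a gut genome collection
so that every pipeline stage admits parameter-recovery tests:

* three default phyla with planted secretion fractions 0.30 / 0.25 / 0.10
  (a Bacteroidetes-like top secretor, a Verrucomicrobia-like runner-up and
  a Firmicutes-like majority phylum);
* secreted proteins drawn longer than nonsecreted ones (lognormal lengths
  with means 482 vs 329 amino acids);
* phylum-specific CAZyme repertoires, with the Bacteroidetes- and
  Verrucomicrobia-like phyla sharing one profile so their repertoires
  co-cluster in ordination;
* protein "base" sequences duplicated across genomes of a phylum with
  ~1% divergence, so true clusters exist above the 95% identity threshold;
* gastrointestinal read sets whose phylum composition shifts along the
  tract and in which chosen EC functions are enriched at chosen
  (site, compartment) habitats.

Every emitted record is tracked in a ledger, and identical seeds reproduce
all outputs byte for byte.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_fasta, write_table
from .model import Mag, Orf, OrfCluster, SampleMeta

AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# Approximate bacterial proteome residue frequencies; only the relative
# magnitudes matter (they make biosynthetic-cost summaries realistic).
AA_FREQS = np.array(
    [0.089, 0.012, 0.054, 0.062, 0.040, 0.078, 0.021, 0.066, 0.058, 0.100,
     0.024, 0.041, 0.043, 0.038, 0.051, 0.059, 0.055, 0.071, 0.012, 0.026]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

# ECs not tied to a CAZyme family, delivered through the orthologous-group
# reference table (nucleotidases, peptidases, a reductase).
GENERIC_ECS = ["3.1.3.5", "3.1.3.6", "3.4.21.107", "3.4.14.5", "1.1.1.169"]

_CODONS = {
    aa: codons
    for aa, codons in {
        "A": ["GCT", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
        "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC"],
        "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
        "L": ["CTG", "TTA"], "M": ["ATG"], "N": ["AAT", "AAC"],
        "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC"],
        "S": ["TCT", "AGC"], "T": ["ACT", "ACC"], "V": ["GTT", "GTC"],
        "W": ["TGG"], "Y": ["TAT", "TAC"],
    }.items()
}


@dataclass(frozen=True)
class PhylumSpec:
    """Planted parameters of one synthetic phylum."""

    name: str
    n_mags: int
    secretion_fraction: float
    mean_len_secreted_aa: float = 482.0
    mean_len_nonsecreted_aa: float = 329.0
    cazyme_profile: dict = field(default_factory=dict)  # family -> expected count/MAG
    cazyme_secretion_fraction: float = 0.105
    cog_rates: dict = field(default_factory=dict)  # category -> relative rate

    def __post_init__(self) -> None:
        for frac in (self.secretion_fraction, self.cazyme_secretion_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.name}: fraction {frac} outside [0, 1]")
        if self.n_mags < 1:
            raise ValueError(f"{self.name}: n_mags must be >= 1")


# Shared Bacteroidetes/Verrucomicrobia-like repertoire: mucin/host-glycan and
# plant-cell-wall hydrolases, plus starch-acting GH13.
BV_CAZYME_PROFILE = {
    "GH2": 3.0, "GH20": 2.0, "GH29": 2.0, "GH33": 1.0, "GH43": 2.5,
    "GH92": 1.5, "GH95": 1.0, "GH13": 2.0, "GH31": 1.0, "GH51": 0.8,
    "GH127": 0.6, "GH109": 0.5,
}
# Firmicutes-like repertoire: cytoplasmic sugar utilisation plus chitinases.
F_CAZYME_PROFILE = {
    "GH1": 2.0, "GH4": 1.0, "GH18": 0.8, "GH13": 1.5, "GH32": 0.8,
    "GH23": 1.0, "GH25": 0.6, "GH73": 0.6, "GH36": 0.5,
}


def default_phyla() -> list[PhylumSpec]:
    return [
        PhylumSpec(
            "Bacteroidetes_like", n_mags=20, secretion_fraction=0.30,
            cazyme_profile=dict(BV_CAZYME_PROFILE), cazyme_secretion_fraction=0.20,
            cog_rates={"G": 4.0, "M": 2.0, "P": 1.0, "E": 1.0, "C": 0.5, "N": 0.3},
        ),
        PhylumSpec(
            "Verrucomicrobia_like", n_mags=20, secretion_fraction=0.25,
            cazyme_profile=dict(BV_CAZYME_PROFILE), cazyme_secretion_fraction=0.18,
            cog_rates={"G": 3.5, "M": 2.0, "P": 1.0, "E": 1.0, "C": 0.5, "N": 0.2},
        ),
        PhylumSpec(
            "Firmicutes_like", n_mags=20, secretion_fraction=0.10,
            cazyme_profile=dict(F_CAZYME_PROFILE), cazyme_secretion_fraction=0.03,
            cog_rates={"G": 1.5, "M": 2.0, "P": 1.5, "E": 1.5, "C": 1.0, "N": 1.0},
        ),
    ]


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of a synthetic community; defaults mirror the study conditions."""

    seed: int = 0
    phyla: tuple = ()
    orfs_per_mag: int = 250
    cluster_redundancy: float = 3.0
    mutation_rate: float = 0.01  # per-residue substitution vs the base protein
    label_noise: float = 0.0  # default prediction-corruption rate
    tm_false_positive_rate: float = 0.0
    length_sigma: float = 0.35  # lognormal shape of protein lengths
    mags_per_otu: int = 1
    with_sequences: bool = True

    def __post_init__(self) -> None:
        phyla = tuple(self.phyla) if self.phyla else tuple(default_phyla())
        object.__setattr__(self, "phyla", phyla)
        for prob in (self.label_noise, self.tm_false_positive_rate, self.mutation_rate):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.cluster_redundancy < 1:
            raise ValueError("cluster_redundancy must be >= 1")
        for spec in phyla:
            if self.cluster_redundancy > spec.n_mags:
                raise ValueError(
                    f"{spec.name}: cluster_redundancy {self.cluster_redundancy} exceeds "
                    f"n_mags {spec.n_mags}; bases could not be spread across genomes"
                )


def small_community_config(seed: int = 0, **overrides) -> CommunityConfig:
    """A desk-scale community (22 genomes, ~900 ORFs) for end-to-end runs
    that include greedy clustering.

    Redundancy 6 keeps typical true-cluster sizes above the >= 5-member
    floor, so the cluster-size filter passes most of the community through
    rather than silencing it."""
    phyla = [
        replace(default_phyla()[0], n_mags=8),
        replace(default_phyla()[1], n_mags=6),
        replace(default_phyla()[2], n_mags=8),
    ]
    return CommunityConfig(
        seed=seed, phyla=tuple(phyla), orfs_per_mag=40, cluster_redundancy=6.0,
        **overrides,
    )


@dataclass
class Community:
    """Generated community: ledger plus (optionally) protein sequences.

    ``ledger`` has one row per ORF with its planted truth: mag, phylum,
    cluster (base protein), secretion class and helix count, CAZyme family,
    EC, COG category and lengths.
    """

    config: CommunityConfig
    ledger: pd.DataFrame
    mag_table: pd.DataFrame  # mag_id, otu_id, phylum, family
    og_reference: pd.DataFrame  # og_id, cog_category, ec
    aa_seqs: dict | None = None

    # -- convenience views -------------------------------------------------
    def orf_to_mag(self) -> dict[str, str]:
        return dict(zip(self.ledger["orf_id"], self.ledger["mag_id"]))

    def mag_to_phylum(self) -> dict[str, str]:
        return dict(zip(self.mag_table["mag_id"], self.mag_table["phylum"]))

    def secretion_truth(self) -> dict[str, bool]:
        return dict(zip(self.ledger["orf_id"], self.ledger["secreted"].astype(bool)))

    def orf_lengths_nt(self) -> dict[str, int]:
        return dict(zip(self.ledger["orf_id"], self.ledger["len_nt"]))

    def orf_ecs(self) -> dict[str, list[str]]:
        return {
            r.orf_id: [r.ec] if r.ec else []
            for r in self.ledger.itertuples()
        }

    def protein_records(self) -> list[tuple[str, str]]:
        if self.aa_seqs is None:
            raise ValueError("community was generated without sequences")
        return [(r.orf_id, self.aa_seqs[r.orf_id]) for r in self.ledger.itertuples()]

    def true_clusters(self) -> list[OrfCluster]:
        """Clusters implied by base-protein ancestry.

        The centroid of each cluster is its longest member (ties broken
        lexicographically by id), matching the greedy clusterer's ordering.
        """
        clusters = []
        for _, grp in self.ledger.groupby("base_id", sort=True):
            ranked = sorted(
                zip(-grp["len_aa"], grp["orf_id"]),
            )
            ids = [orf_id for _, orf_id in ranked]
            clusters.append(OrfCluster(ids[0], tuple(ids)))
        return clusters

    def to_mags(self) -> list[Mag]:
        """Materialize Mag/Orf objects (genes laid head to tail per genome)."""
        mags = {
            r.mag_id: Mag(r.mag_id, r.otu_id, r.phylum, r.family)
            for r in self.mag_table.itertuples()
        }
        cursor: dict[str, int] = {m: 1 for m in mags}
        for r in self.ledger.itertuples():
            start = cursor[r.mag_id]
            end = start + int(r.len_nt) - 1
            cursor[r.mag_id] = end + 101  # 100 nt intergenic spacer
            aa = self.aa_seqs[r.orf_id] if self.aa_seqs is not None else ""
            mags[r.mag_id].orfs.append(
                Orf(r.orf_id, r.mag_id, "c1", start, end, "+", "", aa)
            )
        return list(mags.values())

    def nt_seq(self, orf_id: str) -> str:
        """Deterministic coding sequence for one ORF (derived on demand)."""
        if self.aa_seqs is None:
            raise ValueError("community was generated without sequences")
        rng = np.random.default_rng((self.config.seed, zlib.crc32(orf_id.encode())))
        codons = [
            _CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
            for aa in self.aa_seqs[orf_id]
        ]
        codons.append("TAA")
        return "".join(codons)


_SIGNAL_PEPTIDE = "MKKRLLSALLALGLVSA"  # planted N-terminal export tag
_TAT_PEPTIDE = "MSNRRDFLKAAGALGLAA"  # twin-arginine variant


def _draw_protein(rng: np.random.Generator, length: int, secreted: bool, sp_class: str) -> str:
    body = "".join(rng.choice(AA_LETTERS, size=length, p=AA_FREQS))
    if secreted or sp_class in ("SEC_SPI", "TAT", "LIPO"):
        tag = _TAT_PEPTIDE if sp_class == "TAT" else _SIGNAL_PEPTIDE
        if length > len(tag):
            body = tag + body[len(tag):]
    return body


def generate_community(config: CommunityConfig) -> Community:
    """Generate genomes' worth of proteins with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    base_rows = []
    orf_rows = []
    mag_rows = []
    og_rows = []
    base_seqs: dict[str, str] = {}
    base_counter = 0

    for spec in config.phyla:
        n_orfs_total = spec.n_mags * config.orfs_per_mag
        n_base = max(config.orfs_per_mag, int(round(n_orfs_total / config.cluster_redundancy)))

        # --- base proteins -------------------------------------------------
        secreted = rng.random(n_base) < spec.secretion_fraction
        # CAZyme families are assigned to a disjoint leading block of bases,
        # sized so each genome carries the expected per-MAG family counts.
        fam_of_base = np.array([""] * n_base, dtype=object)
        cursor = 0
        for family in sorted(spec.cazyme_profile):
            expected = spec.cazyme_profile[family]
            n_fam = int(round(expected * spec.n_mags / config.cluster_redundancy))
            n_fam = min(n_fam, n_base - cursor)
            fam_of_base[cursor : cursor + n_fam] = family
            cursor += n_fam
        is_cazyme = fam_of_base != ""
        # CAZyme secretion status follows its own planted fraction.
        secreted[is_cazyme] = rng.random(int(is_cazyme.sum())) < spec.cazyme_secretion_fraction

        mu_sec = np.log(spec.mean_len_secreted_aa) - config.length_sigma**2 / 2
        mu_non = np.log(spec.mean_len_nonsecreted_aa) - config.length_sigma**2 / 2
        lengths = np.where(
            secreted,
            rng.lognormal(mu_sec, config.length_sigma, n_base),
            rng.lognormal(mu_non, config.length_sigma, n_base),
        )
        lengths = np.maximum(lengths.round().astype(int), 60)

        # Signal-peptide class and helix count, consistent with the label.
        sp_class = np.array(["OTHER"] * n_base, dtype=object)
        tm = np.zeros(n_base, dtype=int)
        sec_idx = np.nonzero(secreted)[0]
        sp_class[sec_idx] = np.where(
            rng.random(len(sec_idx)) < 0.85, "SEC_SPI", "TAT"
        )
        non_idx = np.nonzero(~secreted)[0]
        u = rng.random(len(non_idx))
        sp_class[non_idx[u < 0.08]] = "LIPO"
        # membrane proteins: a Sec tag plus transmembrane helices
        anchored = non_idx[(u >= 0.08) & (u < 0.18)]
        sp_class[anchored] = "SEC_SPI"
        tm[anchored] = rng.integers(1, 7, len(anchored))
        plain = non_idx[u >= 0.18]
        tm[plain] = np.where(rng.random(len(plain)) < 0.25, rng.integers(1, 7, len(plain)), 0)

        # COG categories and orthologous groups.
        cats = sorted(spec.cog_rates) if spec.cog_rates else []
        cog = np.array([""] * n_base, dtype=object)
        og = np.array([""] * n_base, dtype=object)
        if cats:
            weights = np.array([spec.cog_rates[c] for c in cats], float)
            weights /= weights.sum()
            has_cog = rng.random(n_base) < 0.8
            cog[has_cog] = rng.choice(np.array(cats, dtype=object), int(has_cog.sum()), p=weights)
        ec = np.array([""] * n_base, dtype=object)
        from .annotate import load_cazyme_reference

        ref = load_cazyme_reference()
        fam_ec = dict(zip(ref["family"], ref["ec"]))
        for i in range(n_base):
            if fam_of_base[i]:
                ec[i] = fam_ec.get(fam_of_base[i], "")
            elif secreted[i] and rng.random() < 0.3:
                ec[i] = GENERIC_ECS[int(rng.integers(len(GENERIC_ECS)))]
        has_og = (cog != "") | ((ec != "") & (fam_of_base == ""))
        for i in np.nonzero(has_og)[0]:
            og[i] = f"OG{base_counter + i:05d}"
            og_rows.append(
                {
                    "og_id": og[i],
                    "cog_category": cog[i],
                    "ec": ec[i] if not fam_of_base[i] else "",
                }
            )

        base_ids = [f"base{base_counter + i:05d}" for i in range(n_base)]
        if config.with_sequences:
            for i, bid in enumerate(base_ids):
                base_seqs[bid] = _draw_protein(rng, int(lengths[i]), bool(secreted[i]), str(sp_class[i]))
        for i, bid in enumerate(base_ids):
            base_rows.append((bid, spec.name))
        base_counter += n_base

        # --- genomes -------------------------------------------------------
        prefix = spec.name.split("_")[0][:4].lower()
        for m in range(spec.n_mags):
            mag_id = f"{prefix}_mag{m:03d}"
            otu_id = f"{prefix}_otu{m // config.mags_per_otu:03d}"
            tax_family = f"{spec.name}_family{m % 2}"
            mag_rows.append(
                {"mag_id": mag_id, "otu_id": otu_id, "phylum": spec.name, "family": tax_family}
            )
            picks = rng.choice(n_base, size=config.orfs_per_mag, replace=False)
            picks.sort()
            for k, b in enumerate(picks):
                orf_rows.append(
                    {
                        "orf_id": f"{mag_id}_{k + 1}",
                        "mag_id": mag_id,
                        "otu_id": otu_id,
                        "phylum": spec.name,
                        "family": tax_family,
                        "base_id": base_ids[b],
                        "secreted": bool(secreted[b]),
                        "sp_class": str(sp_class[b]),
                        "tm_helices": int(tm[b]),
                        "cazy_family": str(fam_of_base[b]),
                        "ec": str(ec[b]),
                        "cog": str(cog[b]),
                        "og": str(og[b]),
                        "len_aa": int(lengths[b]),
                        "len_nt": 3 * (int(lengths[b]) + 1),
                    }
                )

    ledger = pd.DataFrame(orf_rows)
    mag_table = pd.DataFrame(mag_rows)
    og_reference = pd.DataFrame(og_rows, columns=["og_id", "cog_category", "ec"])

    aa_seqs = None
    if config.with_sequences:
        aa_seqs = {}
        n = len(ledger)
        # per-ORF substitutions relative to the base protein
        for r in ledger.itertuples():
            seq = base_seqs[r.base_id]
            nmut = rng.binomial(len(seq), config.mutation_rate)
            if nmut:
                pos = rng.choice(len(seq), size=nmut, replace=False)
                arr = np.array(list(seq))
                arr[pos] = rng.choice(AA_LETTERS, size=nmut, p=AA_FREQS)
                seq = "".join(arr)
            aa_seqs[r.orf_id] = seq
        assert len(aa_seqs) == n
    return Community(config, ledger, mag_table, og_reference, aa_seqs)


# ---------------------------------------------------------------------------
# prediction-file emission
# ---------------------------------------------------------------------------


def _family_hmm_len(family: str) -> int:
    return 150 + zlib.crc32(family.encode()) % 400


def emit_prediction_files(
    community: Community,
    outdir: str | os.PathLike,
    orf_ids: list[str] | None = None,
    label_noise: float | None = None,
    tm_fp_rate: float | None = None,
    seed: int = 0,
    decoy_rate: float = 0.15,
) -> dict:
    """Write SignalP 5.0, TMHMM and HMMER3 domain-table files for a set of ORFs.

    True labels are corrupted independently: with probability
    ``label_noise`` an ORF's signal-peptide class flips between its true
    class and OTHER; with probability ``tm_fp_rate`` an ORF without helices
    gains one. Domain tables include decoy hits failing the downstream
    filters at rate ``decoy_rate``. Returns the file paths, the
    per-ORF emitted labels and the emitted-hit ledger.
    """
    cfg = community.config
    if label_noise is None:
        label_noise = cfg.label_noise
    if tm_fp_rate is None:
        tm_fp_rate = cfg.tm_false_positive_rate
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ledger = community.ledger
    if orf_ids is not None:
        ledger = ledger[ledger["orf_id"].isin(set(orf_ids))]

    sp_label = {"SEC_SPI": "SP(Sec/SPI)", "TAT": "TAT(Tat/SPI)", "LIPO": "LIPO(Sec/SPII)", "OTHER": "OTHER"}
    emitted = []
    sp_lines = ["# SignalP-5.0\tOrganism: Gram-\t(synthetic predictions)",
                "# ID\tPrediction\tSP(Sec/SPI)\tTAT(Tat/SPI)\tLIPO(Sec/SPII)\tOTHER\tCS Position"]
    tm_lines = []
    for r in ledger.itertuples():
        sp = r.sp_class
        if rng.random() < label_noise:
            sp = "OTHER" if sp in ("SEC_SPI", "TAT") else "SEC_SPI"
        tm = int(r.tm_helices)
        if tm == 0 and rng.random() < tm_fp_rate:
            tm = int(rng.integers(1, 3))
        prob = 0.5 + rng.random() / 2
        sp_lines.append(f"{r.orf_id}\t{sp_label[sp]}\t{prob:.4f}\t0.0\t0.0\t0.0\t")
        topo_parts = []
        pos = 7
        for _ in range(tm):
            topo_parts.append(f"{pos}-{pos + 22}")
            pos += 40
        topo = "i" + "o".join(topo_parts) + ("o" if tm % 2 else "i") if tm else "i"
        tm_lines.append(
            f"{r.orf_id}\tlen={r.len_aa}\tExpAA={22.5 * tm:.2f}\tFirst60={min(22.5 * tm, 60):.2f}"
            f"\tPredHel={tm}\tTopology={topo}"
        )
        emitted.append({"orf_id": r.orf_id, "sp_class": sp, "tm_helices": tm})

    signalp_path = outdir / "signalp5_summary.signalp5"
    signalp_path.write_text("\n".join(sp_lines) + "\n")
    tmhmm_path = outdir / "tmhmm_short.txt"
    tmhmm_path.write_text("\n".join(tm_lines) + "\n")

    # --- HMMER3 domain tables ---------------------------------------------
    def domtbl_line(orf_id, family, qlen, evalue, hmm_len, hmm_from, hmm_to, ali_from, ali_to):
        return (
            f"{family}.hmm - {hmm_len} {orf_id} - {qlen} {evalue:.3g} 100.0 0.1 1 1 "
            f"{evalue:.3g} {evalue:.3g} 99.0 0.1 {hmm_from} {hmm_to} {ali_from} {ali_to} "
            f"{ali_from} {ali_to} 0.95 -"
        )

    hit_rows = []
    dbcan_lines = []
    for r in ledger.itertuples():
        if not r.cazy_family:
            continue
        hmm_len = _family_hmm_len(r.cazy_family)
        cov = rng.uniform(0.45, 0.95)
        span = max(int(round(cov * hmm_len)), int(np.ceil(0.35 * hmm_len)) + 1)
        span = min(span, hmm_len)
        hmm_from = int(rng.integers(1, hmm_len - span + 2))
        evalue = 10.0 ** (-rng.uniform(16.5, 40))
        ali_from = int(rng.integers(1, max(2, r.len_aa // 4)))
        ali_to = min(int(r.len_aa), ali_from + span - 1)
        dbcan_lines.append(
            domtbl_line(r.orf_id, r.cazy_family, r.len_aa, evalue, hmm_len, hmm_from,
                        hmm_from + span - 1, ali_from, ali_to)
        )
        hit_rows.append({"orf_id": r.orf_id, "family": r.cazy_family, "survives": True})
        if rng.random() < decoy_rate:
            # decoy failing either the coverage or the e-value threshold
            d_len = _family_hmm_len("GH0")
            if rng.random() < 0.5:
                d_span = max(2, int(0.2 * d_len))
                d_eval = 10.0 ** (-rng.uniform(16.5, 30))
            else:
                d_span = max(int(0.5 * d_len), int(np.ceil(0.35 * d_len)) + 1)
                d_eval = 10.0 ** (-rng.uniform(3, 10))
            d_from = int(rng.integers(1, d_len - d_span + 2))
            d_ali_from = max(1, int(r.len_aa) - d_span)
            dbcan_lines.append(
                domtbl_line(r.orf_id, "GH0", r.len_aa, d_eval, d_len,
                            d_from, d_from + d_span - 1, d_ali_from,
                            min(int(r.len_aa), d_ali_from + d_span - 1))
            )
            hit_rows.append({"orf_id": r.orf_id, "family": "GH0", "survives": False})

    dbcan_path = outdir / "dbcan.domtblout"
    dbcan_path.write_text(
        "#                    --- full sequence --- -------------- this domain --------------\n"
        + "\n".join(dbcan_lines)
        + ("\n" if dbcan_lines else "")
    )

    egg_lines = []
    for r in ledger.itertuples():
        if not r.og:
            continue
        hmm_len = 200
        evalue = 10.0 ** (-rng.uniform(4, 30))
        egg_lines.append(
            domtbl_line(r.orf_id, r.og, r.len_aa, evalue, hmm_len, 1, hmm_len, 1,
                        min(int(r.len_aa), hmm_len))
        )
        if rng.random() < 0.2:  # worse secondary hit, must lose best-hit selection
            egg_lines.append(
                domtbl_line(r.orf_id, f"OGALT{zlib.crc32(r.og.encode()) % 999:03d}",
                            r.len_aa, min(evalue * 1e3, 9e-4), hmm_len, 1, hmm_len, 1,
                            min(int(r.len_aa), hmm_len))
            )
    eggnog_path = outdir / "eggnog.domtblout"
    eggnog_path.write_text("\n".join(egg_lines) + ("\n" if egg_lines else ""))

    og_path = outdir / "og_reference.tsv"
    write_table(community.og_reference, og_path)

    return {
        "signalp": signalp_path,
        "tmhmm": tmhmm_path,
        "dbcan": dbcan_path,
        "eggnog": eggnog_path,
        "og_reference": og_path,
        "emitted_labels": pd.DataFrame(emitted),
        "emitted_hits": pd.DataFrame(hit_rows, columns=["orf_id", "family", "survives"]),
    }


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

DEFAULT_SITES = ["duodenum", "jejunum", "ileum", "cecum", "colon"]


def _default_abundance(phyla: list[str]) -> dict:
    """Phylum composition per habitat: the last phylum (Firmicutes-like)
    dominates the upper GI, the first (Bacteroidetes-like) the lower;
    middle phyla are minor, mucosa-leaning members. Stool mirrors the
    colonic lumen."""
    if len(phyla) == 1:
        only = phyla[0]
        sites = ["duodenum", "jejunum", "ileum", "cecum", "colon"]
        table = {(s, c): {only: 1.0} for s in sites for c in ("lumen", "mucosa")}
        table[("stool", "stool")] = {only: 1.0}
        return table
    b, f = phyla[0], phyla[-1]
    minors = phyla[1:-1]
    grad = {"duodenum": 0.15, "jejunum": 0.22, "ileum": 0.32, "cecum": 0.45, "colon": 0.55}
    table = {}
    for site, b_frac in grad.items():
        for comp in ("lumen", "mucosa"):
            minor_total = (0.08 if comp == "lumen" else 0.16) if minors else 0.0
            comp_table = {b: b_frac, f: 1.0 - b_frac - minor_total}
            for m in minors:
                comp_table[m] = minor_total / len(minors)
            table[(site, comp)] = comp_table
    stool = {b: 0.55, f: 1.0 - 0.55 - (0.08 if minors else 0.0)}
    for m in minors:
        stool[m] = 0.08 / len(minors)
    table[("stool", "stool")] = stool
    return table


@dataclass(frozen=True)
class SamplingConfig:
    """Read-sampling design across GI sites and compartments."""

    sites: tuple = tuple(DEFAULT_SITES)
    phylum_abundance: dict = field(default_factory=dict)  # (site, comp) -> {phylum: frac}
    ec_enrichment: dict = field(default_factory=lambda: {("3.2.1.23", "colon", "lumen"): 4.0})
    reads_per_sample: int = 20_000
    replicates_per_site: int = 2
    include_stool: bool = True

    def habitats(self) -> list[tuple[str, str]]:
        out = [(site, comp) for site in self.sites for comp in ("lumen", "mucosa")]
        if self.include_stool:
            out.append(("stool", "stool"))
        return out

    def validate(self, phyla: list[str]) -> dict:
        table = self.phylum_abundance or _default_abundance(phyla)
        for habitat, comp in table.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"abundances at {habitat} sum to {total}, not 1")
            if any(v < 0 for v in comp.values()):
                raise ValueError(f"negative abundance at {habitat}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        for key, mult in self.ec_enrichment.items():
            if mult < 0:
                raise ValueError(f"negative enrichment multiplier for {key}")
        return table


@dataclass
class ReadSimResult:
    assignments: pd.DataFrame  # read_id, orf_id, sample_id
    sample_meta: list
    ledger: pd.DataFrame  # assignments joined with ORF truth


def generate_reads(
    community: Community, sampling: SamplingConfig | None = None, seed: int = 0
) -> ReadSimResult:
    """Draw reads per sample: a genome bin by habitat-specific phylum
    abundance, then an ORF with probability proportional to its nucleotide
    length times any EC enrichment multiplier for that habitat."""
    sampling = sampling or SamplingConfig()
    phyla = [spec.name for spec in community.config.phyla]
    abundance = sampling.validate(phyla)
    rng = np.random.default_rng(seed)

    ledger = community.ledger
    orf_ids = ledger["orf_id"].to_numpy()
    orf_phyla = ledger["phylum"].to_numpy()
    lengths = ledger["len_nt"].to_numpy(dtype=float)
    ecs = ledger["ec"].to_numpy()

    sample_meta: list[SampleMeta] = []
    frames = []
    for site, comp in sampling.habitats():
        comp_abund = abundance[(site, comp)]
        mult = np.ones(len(ledger))
        for (ec, e_site, e_comp), factor in sampling.ec_enrichment.items():
            if (e_site, e_comp) == (site, comp):
                mult = np.where(ecs == ec, mult * factor, mult)
        weights = lengths * mult
        probs = np.zeros(len(ledger))
        for phylum in phyla:
            mask = orf_phyla == phylum
            total = weights[mask].sum()
            if total > 0:
                probs[mask] = comp_abund.get(phylum, 0.0) * weights[mask] / total
        probs = probs / probs.sum()
        n_rep = 1 if site == "stool" else sampling.replicates_per_site
        for rep in range(n_rep):
            sample_id = f"{site[:4]}_{comp[:3]}_{rep}" if site != "stool" else f"stool_{rep}"
            sample_meta.append(
                SampleMeta(sample_id, site, comp, sampling.reads_per_sample)
            )
            draws = rng.choice(len(orf_ids), size=sampling.reads_per_sample, p=probs)
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": [f"{sample_id}_r{i:06d}" for i in range(len(draws))],
                        "orf_id": orf_ids[draws],
                        "sample_id": sample_id,
                    }
                )
            )
    assignments = pd.concat(frames, ignore_index=True)
    read_ledger = assignments.merge(
        ledger[["orf_id", "phylum", "secreted", "ec", "len_nt"]], on="orf_id", how="left"
    )
    return ReadSimResult(assignments, sample_meta, read_ledger)


def write_sam(
    community: Community,
    assignments: pd.DataFrame,
    sample_id: str,
    path: str | os.PathLike,
    read_length: int = 75,
    seed: int = 0,
) -> None:
    """Write one sample's assignments as a minimal SAM file of primary
    alignments (exercises the SAM ingestion path; no quality strings)."""
    rng = np.random.default_rng(seed)
    sub = assignments[assignments["sample_id"] == sample_id]
    lengths = community.orf_lengths_nt()
    targets = sorted(sub["orf_id"].unique())
    nt_cache: dict[str, str] = {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for orf_id in targets:
            fh.write(f"@SQ\tSN:{orf_id}\tLN:{lengths[orf_id]}\n")
        for r in sub.itertuples():
            ln = lengths[r.orf_id]
            rl = min(read_length, ln)
            pos = int(rng.integers(1, ln - rl + 2))
            if r.orf_id not in nt_cache:
                nt_cache[r.orf_id] = community.nt_seq(r.orf_id)
            seq = nt_cache[r.orf_id][pos - 1 : pos - 1 + rl]
            fh.write(
                f"{r.read_id}\t0\t{r.orf_id}\t{pos}\t42\t{rl}M\t*\t0\t0\t{seq}\t*\n"
            )


def write_community(community: Community, outdir: str | os.PathLike) -> dict:
    """Write proteins, MAG metadata and the ground-truth ledger to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "mag_metadata": outdir / "mag_metadata.tsv",
        "ledger": outdir / "ground_truth.tsv",
    }
    write_fasta(community.protein_records(), paths["proteins"])
    write_table(community.mag_table, paths["mag_metadata"])
    write_table(community.ledger, paths["ledger"])
    return paths
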