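"""Synthetic small-RNA experiment with planted ground truth.

Generates a toy genome carrying gene models, plants MIR hairpin loci inside
dedicated host gene models, plants miRNA target sites (including sites in
epigenetic-regulator transcripts) into other gene models, and simulates the
18 sequencing libraries (2 genotypes x 3 stages x 3 epitype-inducing
temperatures) plus a matched mRNA condition-mean table.  Every planted
feature is recorded in a :class:`GroundTruth` bundle so downstream stages
can be scored by planted-truth recovery.

Read composition follows a configurable length mixture: the 21/22-nt
components are miRNA-derived (planted guides and stars, with isomiR
modification at configured rates), the 24-nt, 31-nt and uniform 15-35 nt
components are genomic background fragments, so the pooled length profile is
tri-modal and spurious read stacks on gene models are possible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sporomir.config import ConfigError, SimConfig, TEMPERATURES
from sporomir.expression import CLUSTER_LABELS
from sporomir.integrate import REGULATOR_CATEGORIES
from sporomir.sequences import DNA, non_pairing_base, revcomp

#: conifer-relevant miRNA family names cycled over the "conserved" loci
FAMILY_POOL = (
    "miR156", "miR159", "miR166", "miR167", "miR319", "miR390", "miR396",
    "miR397", "miR482", "miR946", "miR950", "miR951", "miR1311", "miR1312",
    "miR1316", "miR3701",
)

MIN_EDGE_DISTANCE = 300  # hairpin distance from host gene-model edges


class SizingError(ConfigError):
    """The genome cannot accommodate the requested features."""


@dataclass
class Transcript:
    id: str
    start: int  # 0-based half-open genome coordinates
    end: int
    kind: str  # "mir_host" | "mrna"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MirLocus:
    """A planted hairpin: mature + loop + near-reverse-complement arm."""

    locus_id: str
    host_id: str
    hp_start: int
    hp_end: int
    arm5p: str
    loop: str
    arm3p: str
    guide_arm: str  # "5p" | "3p"
    guide_seq: str
    star_seq: str
    guide_start: int
    guide_end: int
    star_start: int
    star_end: int
    n_designed_mismatches: int
    conserved: bool = False
    family: str | None = None
    ref_id: str | None = None

    @property
    def guide_name(self) -> str:
        return f"{self.locus_id}_{self.guide_arm}"

    @property
    def star_arm(self) -> str:
        return "3p" if self.guide_arm == "5p" else "5p"

    @property
    def star_name(self) -> str:
        return f"{self.locus_id}_{self.star_arm}"

    @property
    def hairpin(self) -> str:
        return self.arm5p + self.loop + self.arm3p


@dataclass
class TargetLink:
    mirna: str  # guide name
    guide_seq: str
    transcript: str
    site_start: int  # transcript-local, 0-based half-open
    site_end: int
    n_mismatches: int
    expected_e: float
    score_class: str
    is_regulator: bool


@dataclass
class GroundTruth:
    """Answer key for the simulated experiment."""

    loci: list[MirLocus]
    family_labels: dict[str, str]  # guide name -> family (conserved only)
    expression_model: dict[str, dict]  # guide name -> base/multipliers/profile
    target_links: list[TargetLink]
    regulator_categories: dict[str, str]  # transcript -> category
    transcripts: list[Transcript] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "loci": [dataclasses.asdict(l) for l in self.loci],
            "family_labels": self.family_labels,
            "expression_model": self.expression_model,
            "target_links": [dataclasses.asdict(t) for t in self.target_links],
            "regulator_categories": self.regulator_categories,
            "transcripts": [dataclasses.asdict(t) for t in self.transcripts],
        }

    @classmethod
    def from_json(cls, data: dict) -> "GroundTruth":
        return cls(
            loci=[MirLocus(**l) for l in data["loci"]],
            family_labels=data["family_labels"],
            expression_model=data["expression_model"],
            target_links=[TargetLink(**t) for t in data["target_links"]],
            regulator_categories=data["regulator_categories"],
            transcripts=[Transcript(**t) for t in data["transcripts"]],
        )


# ---------------------------------------------------------------------------
# genome and locus construction
# ---------------------------------------------------------------------------

def generate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[bytearray, list[Transcript]]:
    """Random genome with non-overlapping gene models.

    The first ``n_mir_loci`` gene models are long enough to host a hairpin
    >=300 nt from both edges; the rest are ordinary mRNA gene models.
    """
    cfg.validate()
    n = cfg.n_transcripts
    n_hosts = min(cfg.n_mir_loci, n)
    lengths = np.concatenate(
        [
            rng.integers(720, 901, size=n_hosts),
            rng.integers(250, 501, size=n - n_hosts),
        ]
    )
    needed = int(lengths.sum()) + (n + 1)
    if needed > cfg.genome_length:
        raise SizingError(
            f"genome_length={cfg.genome_length} too short: need >= {needed} nt "
            f"for {n} gene models (shortfall {needed - cfg.genome_length} nt)"
        )
    slack = cfg.genome_length - int(lengths.sum()) - (n + 1)
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) + 1
    genome = bytearray(
        np.frombuffer(
            np.array(list(DNA), dtype="S1")[rng.integers(0, 4, cfg.genome_length)]
            .tobytes(),
            dtype=np.uint8,
        )
    )
    transcripts = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        kind = "mir_host" if i < n_hosts else "mrna"
        transcripts.append(Transcript(f"g{i + 1:04d}", start, end, kind))
        pos = end
    return genome, transcripts


def _write(genome: bytearray, pos: int, seq: str) -> None:
    genome[pos : pos + len(seq)] = seq.encode("ascii")


def _design_validates(
    genome: bytearray,
    hp_start: int,
    hairpin: str,
    guide_arm: str,
    m: int,
    flank: int = 80,
) -> bool:
    """Would the first discovery window around this hairpin validate?

    Folds the hairpin with its actual genomic flanks using the discovery
    module's folder and duplex rules, so every planted locus is a true
    positive for the pipeline at its first (smallest) window.
    """
    from sporomir.discovery import validate_duplex
    from sporomir.fold import fold

    hp_end = hp_start + len(hairpin)
    left = genome[hp_start - flank : hp_start].decode()
    right = genome[hp_end : hp_end + flank].decode()
    window = left + hairpin + right
    if guide_arm == "5p":
        gs = len(left)
    else:
        gs = len(left) + len(hairpin) - m
    return validate_duplex(fold(window), gs, gs + m).passed


def plant_mir_loci(
    genome: bytearray,
    transcripts: list[Transcript],
    cfg: SimConfig,
    rng: np.random.Generator,
    max_tries: int = 25,
) -> list[MirLocus]:
    """Plant hairpin loci into the host gene models.

    Each locus is mature (21-22 nt) + loop (8-20 nt) + near-reverse-
    complement of the mature with 0-3 designed mismatches; the mismatched
    bases are chosen so they cannot pair the guide (neither Watson-Crick nor
    G:U), making the designed duplex geometry unambiguous.  The guide/star
    duplex carries the canonical 2-nt 3' overhangs, so the star sequence
    extends 2 nt past the opposite arm.  Designs are rejection-sampled
    until the hairpin, folded in its genomic context, passes the discovery
    module's duplex validation.
    """
    w21 = cfg.length_mixture[21]
    w22 = cfg.length_mixture[22]
    p21 = w21 / (w21 + w22) if (w21 + w22) > 0 else 1.0
    hosts = [t for t in transcripts if t.kind == "mir_host"]
    if len(hosts) < cfg.n_mir_loci:
        raise SizingError("not enough host gene models for requested MIR loci")
    loci: list[MirLocus] = []
    seen_guides: set[str] = set()
    for i in range(cfg.n_mir_loci):
        host = hosts[i]
        m = 21 if rng.random() < p21 else 22
        n_mm = int(rng.choice([0, 1, 2, 3], p=[0.30, 0.30, 0.25, 0.15]))
        guide_arm = str(rng.choice(["5p", "3p"]))
        for attempt in range(max_tries):
            loop_len = int(rng.integers(8, 21))
            mature = "".join(rng.choice(list(DNA), size=m))
            if mature in seen_guides:
                continue
            other = list(revcomp(mature))
            # interior mismatch positions, indexed on the partner arm
            mm_pos = rng.choice(np.arange(2, m - 2), size=n_mm, replace=False)
            for j in sorted(int(p) for p in mm_pos):
                guide_base = mature[m - 1 - j]
                other[j] = non_pairing_base(rng, guide_base)
            other = "".join(other)
            arm5p, arm3p = (mature, other) if guide_arm == "5p" else (other, mature)
            hp_len = 2 * m + loop_len
            lo = host.start + MIN_EDGE_DISTANCE
            hi = host.end - MIN_EDGE_DISTANCE - hp_len
            if hi < lo:
                raise SizingError(
                    f"host {host.id} ({host.length} nt) too short for a {hp_len} nt "
                    f"hairpin {MIN_EDGE_DISTANCE} nt from both edges"
                )
            hp_start = int(rng.integers(lo, hi + 1))
            loop = "".join(rng.choice(list(DNA), size=loop_len))
            hairpin = arm5p + loop + arm3p
            if _design_validates(genome, hp_start, hairpin, guide_arm, m):
                break
        seen_guides.add(mature)
        _write(genome, hp_start, hairpin)
        a5 = (hp_start, hp_start + m)
        a3 = (hp_start + m + loop_len, hp_start + hp_len)
        if guide_arm == "5p":
            gs, ge = a5
            ss, se = a3[0] + 2, a3[1] + 2  # star 3' overhang into host context
        else:
            gs, ge = a3
            ss, se = a5[0] + 2, a5[1] + 2  # star 3' overhang into the loop
        star = genome[ss:se].decode()
        loci.append(
            MirLocus(
                locus_id=f"MIR{i + 1:04d}",
                host_id=host.id,
                hp_start=hp_start,
                hp_end=hp_start + hp_len,
                arm5p=arm5p,
                loop=loop,
                arm3p=arm3p,
                guide_arm=guide_arm,
                guide_seq=mature,
                star_seq=star,
                guide_start=gs,
                guide_end=ge,
                star_start=ss,
                star_end=se,
                n_designed_mismatches=n_mm,
            )
        )
    # flag a subset as conserved and give them family labels
    n_cons = int(round(cfg.frac_conserved * cfg.n_mir_loci))
    cons_idx = sorted(rng.choice(cfg.n_mir_loci, size=n_cons, replace=False).tolist())
    for k, idx in enumerate(cons_idx):
        loc = loci[idx]
        loc.conserved = True
        loc.family = FAMILY_POOL[k % len(FAMILY_POOL)]
        loc.ref_id = f"pab-{loc.family}-{k + 1}"
    return loci


# ---------------------------------------------------------------------------
# expression model and target links
# ---------------------------------------------------------------------------

def _profile_multipliers() -> list[tuple[str, dict[int, float]]]:
    """Multiplier triples (over 18/23/28 degC) for the 12 non-flat classes.

    Two-level profiles use 1x/4x, three-level profiles 1x/2x/4x, so the
    extreme contrast of every class is 4-fold.
    """
    out = []
    for triple, (idx, name) in sorted(CLUSTER_LABELS.items(), key=lambda kv: kv[1][0]):
        groups = name.split(">")  # high ... low
        n_levels = len(groups)
        mult: dict[int, float] = {}
        for level, grp in enumerate(groups):  # level 0 = highest
            rank = (n_levels - 1 - level) / (n_levels - 1)
            for temp in grp.split("="):
                mult[int(temp)] = 4.0 ** rank
        out.append((name, mult))
    return out


def build_expression_model(
    loci: list[MirLocus], cfg: SimConfig, rng: np.random.Generator
) -> dict[str, dict]:
    """Per-miRNA base abundance and temperature multipliers.

    A ``frac_de_mirnas`` fraction of loci receives a temperature-dependent
    profile cycling through the 12 non-flat classes (4-fold extreme
    contrast); the rest are flat.
    """
    profiles = _profile_multipliers()
    n = len(loci)
    n_de = int(round(cfg.frac_de_mirnas * n))
    de_idx = sorted(rng.choice(n, size=n_de, replace=False).tolist())
    model: dict[str, dict] = {}
    for i, loc in enumerate(loci):
        base = float(rng.lognormal(0.0, 0.5))
        star_ratio = float(rng.uniform(*cfg.star_ratio_range))
        if i in de_idx:
            name, mult = profiles[de_idx.index(i) % len(profiles)]
        else:
            name, mult = "flat", {t: 1.0 for t in TEMPERATURES}
        model[loc.guide_name] = {
            "locus_id": loc.locus_id,
            "base": base,
            "multipliers": {str(t): mult[t] for t in TEMPERATURES},
            "profile": name,
            "is_de": name != "flat",
            "star_ratio": star_ratio,
        }
    return model


def plant_target_sites(
    genome: bytearray,
    transcripts: list[Transcript],
    loci: list[MirLocus],
    model: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[TargetLink], dict[str, str]]:
    """Write target sites of DE miRNAs into non-host gene models.

    Each DE miRNA gets ``links_per_de_mirna`` sites: the first lands in an
    epigenetic-regulator transcript, the rest in ordinary transcripts.  A
    site is the reverse complement of the guide with 0-2 designed mismatches
    outside the seed region (miRNA positions 2-13), i.e. expectation scores
    0-2 ("strong" sites under a cutoff of 3).
    """
    n_hosts = sum(t.kind == "mir_host" for t in transcripts)
    regulators = transcripts[n_hosts : n_hosts + cfg.n_regulator_transcripts]
    plain = transcripts[n_hosts + cfg.n_regulator_transcripts :]
    categories = {
        t.id: REGULATOR_CATEGORIES[i % len(REGULATOR_CATEGORIES)]
        for i, t in enumerate(regulators)
    }
    reg_pool = list(regulators)
    plain_pool = list(plain)
    rng.shuffle(reg_pool)
    rng.shuffle(plain_pool)
    links: list[TargetLink] = []
    mm_cycle = (0, 1, 2)
    k = 0
    for loc in loci:
        info = model[loc.guide_name]
        if not info["is_de"]:
            continue
        for j in range(cfg.links_per_de_mirna):
            pool = reg_pool if j == 0 else plain_pool
            if not pool:
                break
            tr = pool.pop()
            guide = loc.guide_seq
            m = len(guide)
            site = list(revcomp(guide))
            n_mm = mm_cycle[k % len(mm_cycle)]
            k += 1
            # mismatches at miRNA positions > 13 (outside seed); site index m-p
            pos_choices = np.arange(14, m + 1)
            for p in rng.choice(pos_choices, size=n_mm, replace=False):
                site[m - int(p)] = non_pairing_base(rng, guide[int(p) - 1])
            site = "".join(site)
            lo, hi = tr.start + 30, tr.end - 30 - m
            spos = int(rng.integers(lo, hi + 1))
            _write(genome, spos, site)
            links.append(
                TargetLink(
                    mirna=loc.guide_name,
                    guide_seq=guide,
                    transcript=tr.id,
                    site_start=spos - tr.start,
                    site_end=spos - tr.start + m,
                    n_mismatches=n_mm,
                    expected_e=float(n_mm),
                    score_class="strong",
                    is_regulator=(j == 0),
                )
            )
    return links, categories


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _apply_isomir(
    seq: str, gs: int, ge: int, genome: bytearray, cls: str, rng: np.random.Generator
) -> str:
    if cls == "substitution":
        pos = int(rng.integers(len(seq)))
        alt = str(rng.choice([b for b in DNA if b != seq[pos]]))
        return seq[:pos] + alt + seq[pos + 1 :]
    k = 1 if rng.random() < 0.7 else 2
    if cls == "trim5":
        return seq[k:]
    if cls == "trim3":
        return seq[:-k]
    if cls == "ext_templated":
        if rng.random() < 0.5:
            return genome[gs - k : gs].decode() + seq
        return seq + genome[ge : ge + k].decode()
    if cls == "tail3_U":
        return seq + "T" * k
    if cls == "tail3_A":
        return seq + "A" * k
    raise ValueError(f"unknown isomiR class {cls!r}")


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(k, len(seq)), replace=False):
        out[pos] = str(rng.choice([b for b in DNA if b != out[pos]]))
    return "".join(out)


def simulate_libraries(
    genome: bytearray,
    loci: list[MirLocus],
    model: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator,
    outdir: Path,
) -> "pd.DataFrame":
    """Simulate all libraries as FASTQ files; return the truth count table.

    Reads are a multinomial draw over (per-locus guide, per-locus star,
    background 24 nt, background 31 nt, background uniform 15-35 nt); miRNA
    reads receive isomiR modifications at the configured rates and every
    read receives per-base sequencing errors.  The truth table counts reads
    by origin (guide/star/background) and sums to ``reads_per_library``.
    """
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "libraries").mkdir(parents=True, exist_ok=True)
    gstr = genome.decode()
    rc = revcomp(gstr)
    G = len(gstr)
    mix = cfg.length_mixture
    iso_classes = list(cfg.isomir_rates)
    iso_p = np.array([cfg.isomir_rates[c] for c in iso_classes], dtype=float)
    p_mod = float(iso_p.sum())
    iso_p_norm = iso_p / p_mod if p_mod > 0 else iso_p

    # component layout: guide_i, star_i for each locus, then 3 background bins
    mir_mass = mix[21] + mix[22]
    by_len: dict[int, list[int]] = {21: [], 22: []}
    for idx, loc in enumerate(loci):
        by_len[len(loc.guide_seq)].append(idx)

    origins = [l.guide_name for l in loci] + [l.star_name for l in loci] + ["background"]
    counts = pd.DataFrame(0, index=origins, columns=cfg.library_names, dtype=int)

    # fixed (temperature-averaged) normaliser per length class, so planted
    # fold changes are not attenuated by per-library composition effects
    z0: dict[int, float] = {}
    for length in (21, 22):
        z0[length] = sum(
            model[loci[i].guide_name]["base"]
            * np.mean(list(model[loci[i].guide_name]["multipliers"].values()))
            for i in by_len[length]
        )

    for lib, (geno, stage, temp) in zip(cfg.library_names, cfg.library_design):
        probs = np.zeros(2 * len(loci) + 3)
        for length in (21, 22):
            idxs = by_len[length]
            w_class = mix[length]
            if not idxs:
                continue
            locus_w = np.array(
                [
                    model[loci[i].guide_name]["base"]
                    * model[loci[i].guide_name]["multipliers"][str(temp)]
                    for i in idxs
                ]
            ) / z0[length]
            for w, i in zip(locus_w, idxs):
                ratio = model[loci[i].guide_name]["star_ratio"]
                probs[i] = w_class * w * (ratio / (1.0 + ratio))
                probs[len(loci) + i] = w_class * w * (1.0 / (1.0 + ratio))
        probs[-3] = mix[24]
        probs[-2] = mix[31]
        probs[-1] = mix["uniform"]
        if not by_len[21] and not by_len[22]:
            probs[-1] += mir_mass  # no loci: miRNA mass becomes background
        probs /= probs.sum()
        draw = rng.multinomial(cfg.reads_per_library, probs)

        reads: list[str] = []
        for i, loc in enumerate(loci):
            for which, c in (("guide", draw[i]), ("star", draw[len(loci) + i])):
                if c == 0:
                    continue
                if which == "guide":
                    seq, s0, s1 = loc.guide_seq, loc.guide_start, loc.guide_end
                    counts.loc[loc.guide_name, lib] += int(c)
                else:
                    seq, s0, s1 = loc.star_seq, loc.star_start, loc.star_end
                    counts.loc[loc.star_name, lib] += int(c)
                n_mod = int(rng.binomial(c, p_mod)) if p_mod > 0 else 0
                reads.extend([seq] * (int(c) - n_mod))
                for _ in range(n_mod):
                    cls = iso_classes[int(rng.choice(len(iso_classes), p=iso_p_norm))]
                    reads.append(_apply_isomir(seq, s0, s1, genome, cls, rng))
        for length, c in ((24, draw[-3]), (31, draw[-2])):
            if c == 0:
                continue
            starts = rng.integers(0, G - length, size=int(c))
            strands = rng.integers(0, 2, size=int(c))
            src = (gstr, rc)
            reads.extend(src[int(st)][p : p + length] for p, st in zip(starts, strands))
        c = int(draw[-1])
        if c:
            lens = rng.integers(15, 36, size=c)
            starts = rng.integers(0, G - 36, size=c)
            strands = rng.integers(0, 2, size=c)
            src = (gstr, rc)
            reads.extend(
                src[int(st)][p : p + int(ln)]
                for p, st, ln in zip(starts, strands, lens)
            )
        counts.loc["background", lib] = int(draw[-3] + draw[-2] + draw[-1])

        if cfg.seq_error_rate > 0:
            lens = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
            n_err = rng.binomial(lens, cfg.seq_error_rate)
            for ridx in np.nonzero(n_err)[0]:
                reads[ridx] = _mutate(reads[ridx], int(n_err[ridx]), rng)

        with open(outdir / "libraries" / f"{lib}.fastq", "w") as fh:
            fh.write(
                "".join(
                    f"@{lib}:{i}\n{s}\n+\n{'?' * len(s)}\n" for i, s in enumerate(reads)
                )
            )
    return counts


# ---------------------------------------------------------------------------
# mRNA expression table
# ---------------------------------------------------------------------------

def simulate_mrna_expression(
    transcripts: list[Transcript],
    links: list[TargetLink],
    model: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> "pd.DataFrame":
    """Transcript x condition mean-expression table.

    Linked targets are constructed so their *sample* Pearson correlation
    with the linking miRNA's condition profile equals the configured
    anti-correlation strength exactly (the residual direction is the unique
    vector orthogonal to the profile in the centered 3-point space); with
    strength -1 the profile is an exact negative affine image.  Unlinked
    transcripts get independent lognormal profiles.
    """
    import pandas as pd

    conds = [str(t) for t in TEMPERATURES]
    rho = abs(cfg.anticorrelation_strength)
    by_transcript: dict[str, TargetLink] = {}
    for lk in links:
        by_transcript.setdefault(lk.transcript, lk)
    rows = {}
    ones = np.ones(3)
    for tr in transcripts:
        lk = by_transcript.get(tr.id)
        mu = float(rng.lognormal(np.log(100.0), 0.6))
        if lk is None:
            prof = mu * rng.lognormal(0.0, 0.35, size=3)
        else:
            m = np.array(
                [model[lk.mirna]["multipliers"][c] for c in conds], dtype=float
            )
            u = m - m.mean()
            nu = np.linalg.norm(u)
            if nu == 0:
                prof = mu * rng.lognormal(0.0, 0.35, size=3)
            else:
                u_hat = u / nu
                e = np.cross(ones, u_hat)
                e_hat = e / np.linalg.norm(e)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                d = -rho * u_hat + np.sqrt(max(0.0, 1.0 - rho**2)) * sign * e_hat
                kappa = 0.8 / np.abs(d).max()
                prof = mu * (1.0 + kappa * d)
        rows[tr.id] = prof
    return pd.DataFrame.from_dict(rows, orient="index", columns=conds)


# ---------------------------------------------------------------------------
# output writers and orchestration
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, transcripts: list[Transcript], loci: list[MirLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            fh.write(
                f"toygenome\tsporomir\tgene\t{t.start + 1}\t{t.end}\t.\t+\t.\t"
                f"ID={t.id};kind={t.kind}\n"
            )
        for l in loci:
            fh.write(
                f"toygenome\tsporomir\tmiRNA_primary_transcript\t{l.hp_start + 1}\t"
                f"{l.hp_end}\t.\t+\t.\tID={l.locus_id};host={l.host_id}\n"
            )


@dataclass
class SimulationResult:
    truth: GroundTruth
    genome: str
    outdir: Path
    truth_counts: "pd.DataFrame"
    mrna: "pd.DataFrame"

    @property
    def library_paths(self) -> list[Path]:
        return [
            self.outdir / "libraries" / f"{lib}.fastq"
            for lib in [p.stem for p in sorted((self.outdir / "libraries").glob("*.fastq"))]
        ]


def simulate(cfg: SimConfig, outdir: str | Path) -> SimulationResult:
    """Run the full generator and write every pipeline input to ``outdir``.

    Outputs: genome.fa, transcripts.fa, annotations.gff3, libraries/*.fastq,
    reference_matures.fa (+ families and genomic-flank sidecars),
    mrna_expression.tsv, regulator_annotation.tsv, library_metadata.tsv,
    truth_counts.tsv and truth.json.  Byte-identical under a fixed seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, transcripts = generate_genome(cfg, rng)
    loci = plant_mir_loci(genome, transcripts, cfg, rng)
    model = build_expression_model(loci, cfg, rng)
    links, categories = plant_target_sites(genome, transcripts, loci, model, cfg, rng)
    truth_counts = simulate_libraries(genome, loci, model, cfg, rng, outdir)
    mrna = simulate_mrna_expression(transcripts, links, model, cfg, rng)

    gstr = genome.decode()
    _write_fasta(outdir / "genome.fa", [("toygenome", gstr)])
    _write_fasta(
        outdir / "transcripts.fa",
        [(t.id, gstr[t.start : t.end]) for t in transcripts],
    )
    _write_gff3(outdir / "annotations.gff3", transcripts, loci)

    conserved = [l for l in loci if l.conserved]
    _write_fasta(
        outdir / "reference_matures.fa", [(l.ref_id, l.guide_seq) for l in conserved]
    )
    with open(outdir / "reference_families.tsv", "w") as fh:
        fh.write("id\tfamily\n")
        for l in conserved:
            fh.write(f"{l.ref_id}\t{l.family}\n")
    with open(outdir / "reference_flanks.tsv", "w") as fh:
        fh.write("id\tflank5\tflank3\n")
        for l in conserved:
            fh.write(
                f"{l.ref_id}\t{gstr[l.guide_start - 10 : l.guide_start]}\t"
                f"{gstr[l.guide_end : l.guide_end + 10]}\n"
            )
    mrna.rename_axis("transcript").to_csv(outdir / "mrna_expression.tsv", sep="\t")
    with open(outdir / "regulator_annotation.tsv", "w") as fh:
        fh.write("transcript\tcategory\n")
        for tid, cat in categories.items():
            fh.write(f"{tid}\t{cat}\n")
    with open(outdir / "library_metadata.tsv", "w") as fh:
        fh.write("library\tgenotype\tstage\ttemperature\n")
        for lib, (g, s, t) in zip(cfg.library_names, cfg.library_design):
            fh.write(f"{lib}\t{g}\t{s}\t{t}\n")
    truth_counts.rename_axis("origin").to_csv(outdir / "truth_counts.tsv", sep="\t")

    truth = GroundTruth(
        loci=loci,
        family_labels={l.guide_name: l.family for l in conserved},
        expression_model=model,
        target_links=links,
        regulator_categories=categories,
        transcripts=transcripts,
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return SimulationResult(truth, gstr, outdir, truth_counts, mrna)
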