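"""Seeded synthetic inputs for the whole pipeline.

:func:`generate_corpus` emulates a multi-provider interaction snapshot: a
PSI-MITAB 2.5 file with duplicate, unmappable and off-category rows mixed
in, an identifier map, an interolog table, a technique-reliability table, a
small ontology with gene-term associations, a gene x tissue TPM matrix,
receptor/TF role lists and a curated effect table.  A ground-truth sidecar
(true pair list and per-pair evidence tallies) is written alongside so
tests can check the pipeline's bookkeeping exactly.

:func:`hippo_fixture` packages a miniature Hippo signaling cascade
(Stk4/Sav1 -> Lats2 -> Yap1/Wwtr1 -> Tead4) with a two-context expression
matrix: in the trophoblast context the whole cascade is co-expressed, while
in the stem-cell context Tead4 is below the presence threshold, so the
Yap1-Tead4 interaction drops out of the context-specific subnetwork.
All identifiers in both fixtures are synthetic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

#: Technique pool for generated corpora: (MI code, name, reliability).
DEFAULT_TECHNIQUE_POOL: tuple[tuple[str, str, float], ...] = (
    ("MI:0077", "nuclear magnetic resonance", 10.0),
    ("MI:0067", "light scattering", 10.0),
    ("MI:0018", "two hybrid", 5.0),
    ("MI:0019", "coimmunoprecipitation", 5.0),
    ("MI:0416", "fluorescence microscopy", 1.0),
    ("MI:0231", "rnai", 1.0),
    ("MI:0096", "pull down", 7.0),
    ("MI:0107", "surface plasmon resonance", 9.0),
)

_ALLOWED_TYPES = ("MI:0914", "MI:0915", "MI:0407", "MI:0403")
_DISALLOWED_TYPE = "MI:0208"  # genetic interaction: outside the whitelist

_INTEROLOG_TAXA = ("9606", "559292", "7227", "6239", "7955")


@dataclass
class FixtureSpec:
    """Parameters of a generated corpus; identical seed+spec -> identical bytes."""

    seed: int = 0
    n_proteins: int = 80
    n_interactions: int = 150
    duplicate_rate: float = 0.1
    unmappable_rate: float = 0.1
    disallowed_type_rate: float = 0.05
    mean_extra_studies: float = 1.0
    max_techniques_per_study: int = 2
    interolog_coverage: float = 0.4
    max_interolog_species: int = 3
    n_tissues: int = 8
    presence_probability: float = 0.5
    ontology_depth: int = 3
    ontology_branching: int = 3
    max_terms_per_gene: int = 3
    receptor_fraction: float = 0.1
    tf_fraction: float = 0.1
    effect_fraction: float = 0.2

    def validate(self) -> None:
        for name in (
            "duplicate_rate",
            "unmappable_rate",
            "disallowed_type_rate",
            "interolog_coverage",
            "presence_probability",
            "receptor_fraction",
            "tf_fraction",
            "effect_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins < 2 or self.n_interactions < 1:
            raise ValueError("need at least 2 proteins and 1 interaction")


def _mitab_line(
    id_a: str,
    id_b: str,
    method: str,
    pub: str,
    itype: str,
    source: str = "fixdb",
) -> str:
    def mi(code: str) -> str:
        return f'psi-mi:"{code}"(synthetic term)' if code != "-" else "-"

    return "\t".join(
        [
            id_a,
            id_b,
            "-",
            "-",
            "-",
            "-",
            mi(method),
            "-",
            pub,
            "taxid:10090(mouse)",
            "taxid:10090(mouse)",
            mi(itype),
            source,
            "-",
            "-",
        ]
    )


def generate_corpus(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a full synthetic input set plus ground-truth sidecar.

    Returns the manifest (paths of every emitted file and the spec used),
    which is also written to ``manifest.json``.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # --- proteins and identifier map -------------------------------------
    entrez = [100001 + i for i in range(spec.n_proteins)]
    provider = {e: f"fixdb:PRV{e}" for e in entrez}
    idmap_rows = [
        (
            provider[e],
            e,
            f"Gm{e - 100000 + 1000}",
            f"MGI:{e + 100000}",
            f"Q{e - 100000:05d}",
        )
        for e in entrez
    ]
    idmap_path = outdir / "idmap.tsv"
    with open(idmap_path, "w") as fh:
        for row in idmap_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    # --- true pairs and evidence -----------------------------------------
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < spec.n_interactions:
        a, b = rng.choice(entrez, size=2, replace=False)
        pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    pair_list = sorted(pairs)

    pool_codes = [c for c, _, _ in DEFAULT_TECHNIQUE_POOL]
    base_rows: list[tuple[str, str, str, str, str]] = []
    truth_evidence: dict[str, dict] = {}
    study_counter = 10000
    for a, b in pair_list:
        n_studies = 1 + int(rng.poisson(spec.mean_extra_studies))
        studies, techniques, itypes = [], set(), set()
        for _ in range(n_studies):
            study_counter += 1
            pub = f"pubmed:{study_counter}"
            studies.append(pub)
            k = int(rng.integers(1, spec.max_techniques_per_study + 1))
            chosen = rng.choice(pool_codes, size=k, replace=False)
            itype = _ALLOWED_TYPES[int(rng.integers(len(_ALLOWED_TYPES)))]
            itypes.add(itype)
            for code in chosen:
                techniques.add(str(code))
                base_rows.append(
                    (provider[a], provider[b], str(code), pub, itype)
                )
        truth_evidence[f"{a}-{b}"] = {
            "studies": sorted(studies),
            "techniques": sorted(techniques),
            "interaction_types": sorted(itypes),
            "interolog_species": [],
        }

    # --- interologs -------------------------------------------------------
    interolog_path = outdir / "interologs.tsv"
    with open(interolog_path, "w") as fh:
        for a, b in pair_list:
            if rng.random() < spec.interolog_coverage:
                k = int(rng.integers(1, spec.max_interolog_species + 1))
                taxa = sorted(
                    str(t) for t in rng.choice(_INTEROLOG_TAXA, size=k, replace=False)
                )
                truth_evidence[f"{a}-{b}"]["interolog_species"] = taxa
                fh.write(f"{a}\t{b}\t{','.join(taxa)}\n")

    # --- noise rows: duplicates, off-category, unmappable ----------------
    n_dup = int(round(spec.duplicate_rate * len(base_rows)))
    dup_rows = [
        base_rows[int(i)]
        for i in rng.integers(len(base_rows), size=n_dup)
    ]

    n_dis = int(round(spec.disallowed_type_rate * len(base_rows)))
    dis_rows = []
    for _ in range(n_dis):
        a, b = rng.choice(entrez, size=2, replace=False)
        study_counter += 1
        dis_rows.append(
            (
                provider[int(a)],
                provider[int(b)],
                str(rng.choice(pool_codes)),
                f"pubmed:{study_counter}",
                _DISALLOWED_TYPE,
            )
        )

    n_unm = int(round(spec.unmappable_rate * len(base_rows)))
    unm_rows = []
    unm_tally = {"unmapped_a": 0, "unmapped_b": 0, "unmapped_both": 0}
    for j in range(n_unm):
        mode = int(rng.integers(3))  # 0: A unmapped, 1: B unmapped, 2: both
        bad_a = f"fixdb:UNK{j:04d}A"
        bad_b = f"fixdb:UNK{j:04d}B"
        good = provider[int(rng.choice(entrez))]
        study_counter += 1
        pub = f"pubmed:{study_counter}"
        code = str(rng.choice(pool_codes))
        itype = _ALLOWED_TYPES[int(rng.integers(len(_ALLOWED_TYPES)))]
        if mode == 0:
            unm_rows.append((bad_a, good, code, pub, itype))
            unm_tally["unmapped_a"] += 1
        elif mode == 1:
            unm_rows.append((good, bad_b, code, pub, itype))
            unm_tally["unmapped_b"] += 1
        else:
            unm_rows.append((bad_a, bad_b, code, pub, itype))
            unm_tally["unmapped_both"] += 1

    all_rows = base_rows + dup_rows + dis_rows + unm_rows
    order = rng.permutation(len(all_rows))
    mitab_path = outdir / "interactions.mitab"
    with open(mitab_path, "w") as fh:
        fh.write("#ID(A)\tID(B)\tAltID(A)\tAltID(B)\tAlias(A)\tAlias(B)\t"
                 "Method\tAuthor\tPublication\tTaxid(A)\tTaxid(B)\tType\t"
                 "SourceDB\tInteractionID\tConfidence\n")
        for i in order:
            a, b, code, pub, itype = all_rows[int(i)]
            fh.write(_mitab_line(a, b, code, pub, itype) + "\n")

    # --- reliability table ------------------------------------------------
    reliability_path = outdir / "reliability.tsv"
    with open(reliability_path, "w") as fh:
        fh.write("mi_code\tname\treliability\n")
        for code, name, rel in DEFAULT_TECHNIQUE_POOL:
            fh.write(f"{code}\t{name}\t{rel}\n")

    # --- ontology and gene-term associations ------------------------------
    levels: list[list[str]] = [["T0000"]]
    term_counter = 1
    ontology_path = outdir / "ontology.tsv"
    with open(ontology_path, "w") as fh:
        for depth in range(1, spec.ontology_depth + 1):
            level = []
            for parent in levels[-1]:
                for _ in range(spec.ontology_branching):
                    term = f"T{term_counter:04d}"
                    term_counter += 1
                    relation = "is_a" if rng.random() < 0.8 else "part_of"
                    fh.write(f"{term}\t{parent}\t{relation}\n")
                    level.append(term)
            levels.append(level)
    all_terms = [t for lvl in levels for t in lvl]

    annotations_path = outdir / "annotations.tsv"
    with open(annotations_path, "w") as fh:
        for e in entrez:
            k = int(rng.integers(0, spec.max_terms_per_gene + 1))
            if k:
                for term in sorted(
                    str(t) for t in rng.choice(all_terms, size=k, replace=False)
                ):
                    fh.write(f"{e}\t{term}\n")

    # --- expression matrix ------------------------------------------------
    contexts = [f"tissue_{i:02d}" for i in range(spec.n_tissues)]
    expression_path = outdir / "expression.tsv"
    with open(expression_path, "w") as fh:
        fh.write("entrez\t" + "\t".join(contexts) + "\n")
        for e in entrez:
            tpms = []
            for _ in contexts:
                if rng.random() < spec.presence_probability:
                    tpms.append(1.0 + float(rng.exponential(20.0)))
                else:
                    tpms.append(float(rng.uniform(0.0, 0.999)))
            fh.write(f"{e}\t" + "\t".join(f"{v:.4f}" for v in tpms) + "\n")

    # --- roles and effects ------------------------------------------------
    n_rec = max(1, int(round(spec.receptor_fraction * spec.n_proteins)))
    n_tf = max(1, int(round(spec.tf_fraction * spec.n_proteins)))
    receptors = sorted(int(e) for e in rng.choice(entrez, size=n_rec, replace=False))
    tfs = sorted(int(e) for e in rng.choice(entrez, size=n_tf, replace=False))
    receptors_path = outdir / "receptors.tsv"
    tfs_path = outdir / "tfs.tsv"
    receptors_path.write_text("".join(f"{e}\n" for e in receptors))
    tfs_path.write_text("".join(f"{e}\n" for e in tfs))

    effects_path = outdir / "effects.tsv"
    with open(effects_path, "w") as fh:
        for a, b in pair_list:
            if rng.random() < spec.effect_fraction:
                src, tgt = (a, b) if rng.random() < 0.5 else (b, a)
                effect = "activation" if rng.random() < 0.6 else "inhibition"
                fh.write(f"{src}\t{tgt}\t{effect}\n")

    # --- sidecar truth and manifest ---------------------------------------
    truth = {
        "pairs": [list(p) for p in pair_list],
        "evidence": truth_evidence,
        "row_counts": {
            "total": len(all_rows),
            "base": len(base_rows),
            "duplicates": n_dup,
            "disallowed_type": n_dis,
            "unmappable": n_unm,
            **unm_tally,
            "kept_after_filter_and_map": len(base_rows) + n_dup,
        },
        "receptors": receptors,
        "tfs": tfs,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    manifest = {
        "spec": asdict(spec),
        "files": {
            "mitab": str(mitab_path),
            "idmap": str(idmap_path),
            "interologs": str(interolog_path),
            "reliability": str(reliability_path),
            "ontology": str(ontology_path),
            "annotations": str(annotations_path),
            "expression": str(expression_path),
            "receptors": str(receptors_path),
            "tfs": str(tfs_path),
            "effects": str(effects_path),
            "truth": str(truth_path),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


#: Hippo cascade fixture genes: symbol -> synthetic Entrez ID.
HIPPO_GENES = {
    "Stk4": 101,
    "Sav1": 102,
    "Lats2": 103,
    "Yap1": 104,
    "Wwtr1": 105,
    "Tead4": 106,
}

#: Cascade edges: kinase module (Stk4-Sav1, Stk4-Lats2), substrate links
#: (Lats2-Yap1, Lats2-Wwtr1) and coactivator-TF links (Yap1/Wwtr1-Tead4).
HIPPO_EDGES = [
    ("Stk4", "Sav1"),
    ("Stk4", "Lats2"),
    ("Lats2", "Yap1"),
    ("Lats2", "Wwtr1"),
    ("Yap1", "Tead4"),
    ("Wwtr1", "Tead4"),
]


def hippo_fixture(outdir: str | Path) -> dict:
    """Write the packaged Hippo-cascade fixture (deterministic, no RNG).

    Every edge carries three studies, two high-reliability techniques and
    one interolog species, so all scores clear the medium-confidence preset
    (0.53) and confidence filtering never breaks the use case.  Stk4 is
    listed in the receptor role file so that default source/sink endpoint
    selection resolves on this fixture (a fixture convenience: biologically
    Stk4 is a cytoplasmic kinase, and the published use case sets the
    source by hand).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = HIPPO_GENES

    idmap_path = outdir / "idmap.tsv"
    with open(idmap_path, "w") as fh:
        for symbol, e in genes.items():
            fh.write(
                f"fixdb:{symbol.upper()}\t{e}\t{symbol}\t"
                f"MGI:{e + 3000000}\tP{e:05d}\n"
            )

    mitab_path = outdir / "interactions.mitab"
    interolog_path = outdir / "interologs.tsv"
    with open(mitab_path, "w") as mt, open(interolog_path, "w") as il:
        mt.write("#" + "\t".join(f"col{i}" for i in range(1, 16)) + "\n")
        for idx, (sa, sb) in enumerate(HIPPO_EDGES):
            ida, idb = f"fixdb:{sa.upper()}", f"fixdb:{sb.upper()}"
            # three studies; techniques NMR + two-hybrid (reliability 15)
            for k, method in enumerate(["MI:0077", "MI:0018", "MI:0018"]):
                pub = f"pubmed:9{idx:02d}{k}"
                mt.write(
                    _mitab_line(ida, idb, method, pub, "MI:0915") + "\n"
                )
            a, b = sorted((genes[sa], genes[sb]))
            il.write(f"{a}\t{b}\t9606\n")

    reliability_path = outdir / "reliability.tsv"
    with open(reliability_path, "w") as fh:
        fh.write("mi_code\tname\treliability\n")
        for code, name, rel in DEFAULT_TECHNIQUE_POOL:
            fh.write(f"{code}\t{name}\t{rel}\n")

    contexts = ["trophoblast", "stem cell"]
    expression_path = outdir / "expression.tsv"
    with open(expression_path, "w") as fh:
        fh.write("entrez\t" + "\t".join(contexts) + "\n")
        for symbol, e in genes.items():
            # Tead4 falls below the 1-TPM presence call in the stem-cell
            # context only; everything else is co-expressed in both.
            stem = 0.2 if symbol == "Tead4" else 5.0
            fh.write(f"{e}\t5.0\t{stem}\n")

    receptors_path = outdir / "receptors.tsv"
    receptors_path.write_text(f"{genes['Stk4']}\n")
    tfs_path = outdir / "tfs.tsv"
    tfs_path.write_text(f"{genes['Tead4']}\n")

    effects_path = outdir / "effects.tsv"
    with open(effects_path, "w") as fh:
        fh.write(f"{genes['Stk4']}\t{genes['Lats2']}\tactivation\n")
        fh.write(f"{genes['Lats2']}\t{genes['Yap1']}\tinhibition\n")
        fh.write(f"{genes['Lats2']}\t{genes['Wwtr1']}\tinhibition\n")
        fh.write(f"{genes['Yap1']}\t{genes['Tead4']}\tactivation\n")

    ontology_path = outdir / "ontology.tsv"
    ontology_path.write_text("HIPPO_SIGNALING\tSIGNAL_TRANSDUCTION\tis_a\n")
    annotations_path = outdir / "annotations.tsv"
    annotations_path.write_text(
        "".join(f"{e}\tHIPPO_SIGNALING\n" for e in genes.values())
    )

    manifest = {
        "genes": genes,
        "files": {
            "mitab": str(mitab_path),
            "idmap": str(idmap_path),
            "interologs": str(interolog_path),
            "reliability": str(reliability_path),
            "ontology": str(ontology_path),
            "annotations": str(annotations_path),
            "expression": str(expression_path),
            "receptors": str(receptors_path),
            "tfs": str(tfs_path),
            "effects": str(effects_path),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
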