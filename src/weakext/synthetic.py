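"""Synthetic study-condition generators.

Everything downstream of a curated database can be exercised without any
download: (i) committee vote matrices drawn from known ground-truth
labels and per-classifier error rates, and (ii) miniature article
corpora with planted target mentions, distractors, and curated records
exhibiting the terminology mismatch (synonyms, typos) and label noise
that make curated data imperfect training examples.

The bundled vocabularies are small, hand-written lists: ~40 phenotypes
with synonyms, and 14 top-level ethnicity groups with ~60 surface terms
(country adjectivals and demonyms), mirroring the scale at which curated
GWAS resources group ancestry. The sample-description and stage-cue
lexicons are best-effort reconstructions of the kind of term lists a
curation-aware rule classifier would use, not anyone's exact lists.

All generators are deterministic functions of their config seed and emit
the same objects (and, through :func:`save_corpus`, the same file
formats) that the real readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .committee import CommitteeMatrix
from .corpus import (Article, CuratedRecord, RuleLexicon, TermDictionary,
                     dump_dictionary, dump_lexicon, write_article,
                     write_curated_table)
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Bundled vocabularies (synthetic stand-ins, not licensed resources)
# ---------------------------------------------------------------------------

#: canonical phenotype -> synonym surface forms
PHENOTYPES: dict[str, list[str]] = {
    "Type 2 diabetes": ["Type-2 diabetes", "diabetes mellitus type 2"],
    "Type 1 diabetes": ["insulin-dependent diabetes"],
    "Obesity": ["adiposity"],
    "Body mass index": ["BMI"],
    "Waist circumference": [],
    "Height": ["adult height"],
    "Hypertension": ["high blood pressure"],
    "Coronary artery disease": ["coronary heart disease"],
    "Myocardial infarction": ["heart attack"],
    "Atrial fibrillation": [],
    "Stroke": ["ischemic stroke"],
    "LDL cholesterol": ["low-density lipoprotein cholesterol"],
    "HDL cholesterol": ["high-density lipoprotein cholesterol"],
    "Triglycerides": [],
    "Asthma": [],
    "Chronic obstructive pulmonary disease": ["COPD"],
    "Crohn's disease": [],
    "Ulcerative colitis": [],
    "Celiac disease": ["coeliac disease"],
    "Rheumatoid arthritis": [],
    "Systemic lupus erythematosus": ["lupus"],
    "Psoriasis": [],
    "Multiple sclerosis": [],
    "Parkinson's disease": [],
    "Alzheimer's disease": ["late-onset Alzheimer disease"],
    "Schizophrenia": [],
    "Bipolar disorder": ["manic depression"],
    "Major depressive disorder": ["unipolar depression"],
    "Autism spectrum disorder": ["autism"],
    "Attention deficit hyperactivity disorder": ["ADHD"],
    "Breast cancer": [],
    "Prostate cancer": [],
    "Colorectal cancer": ["colon cancer"],
    "Lung cancer": [],
    "Melanoma": ["cutaneous melanoma"],
    "Glaucoma": ["primary open-angle glaucoma"],
    "Age-related macular degeneration": [],
    "Osteoporosis": ["low bone mineral density"],
    "Gout": [],
    "Chronic kidney disease": [],
    "Fasting glucose": ["fasting plasma glucose"],
    "Uric acid levels": ["serum urate"],
}

#: 14 top-level ethnicity groups -> surface terms (adjectivals/demonyms)
ETHNICITY_GROUPS: dict[str, list[str]] = {
    "European": ["European", "Europeans", "Caucasian", "German", "Germans",
                 "French", "Italian", "Italians", "Swedish", "Swedes",
                 "Finnish", "Finns", "British", "Dutch", "Icelandic"],
    "East Asian": ["East Asian", "Chinese", "Han Chinese", "Japanese",
                   "Korean", "Koreans", "Taiwanese"],
    "South Asian": ["South Asian", "Indian", "Indians", "Pakistani",
                    "Bangladeshi", "Sri Lankan"],
    "Southeast Asian": ["Southeast Asian", "Thai", "Vietnamese", "Filipino",
                        "Indonesian", "Malay"],
    "Central Asian": ["Central Asian", "Uzbek", "Kazakh"],
    "African": ["African", "Africans", "Nigerian", "Yoruba", "Kenyan",
                "Gambian"],
    "African American": ["African American", "African-American",
                         "African Americans"],
    "Middle East/North African": ["Middle Eastern", "North African",
                                  "Egyptian", "Moroccan", "Lebanese",
                                  "Iranian"],
    "Hispanic or Latin American": ["Hispanic", "Latino", "Mexican",
                                   "Puerto Rican", "Colombian"],
    "Native American": ["Native American", "Pima", "Navajo"],
    "Oceanian": ["Oceanian", "Papuan", "Aboriginal Australian"],
    "Pacific Islander": ["Pacific Islander", "Samoan", "Tongan"],
    "Ashkenazi Jewish": ["Ashkenazi", "Ashkenazi Jewish"],
    "South American Indigenous": ["Quechua", "Mapuche"],
}

#: sample-description cue terms (reconstructed list, 65 terms)
SAMPLE_DESCRIPTION_TERMS: tuple[str, ...] = (
    "cohort", "cohorts", "participant", "participants", "subject", "subjects",
    "individuals", "patients", "cases", "controls", "sample", "samples",
    "stage", "stages", "phase", "recruited", "recruitment", "enrolled",
    "enrollment", "genotyped", "genotyping", "population", "populations",
    "volunteers", "donors", "probands", "families", "trios", "pedigrees",
    "twins", "adults", "children", "men", "women", "males", "females",
    "ascertained", "consented", "examined", "screened", "studied",
    "surveyed", "registry", "biobank", "panel", "case-control",
    "community-based", "population-based", "hospital-based", "study sample",
    "study population", "sample size", "unrelated", "healthy", "affected",
    "unaffected", "carriers", "respondents", "residents", "attendees",
    "inpatients", "outpatients", "newborns", "adolescents", "elderly",
)

#: stage cue terms (reconstructed, 8 terms total)
INITIAL_CUE_TERMS: tuple[str, ...] = ("discovery", "initial", "screening",
                                      "first stage")
REPLICATION_CUE_TERMS: tuple[str, ...] = ("replication", "follow-up",
                                          "validation", "second stage")

_FILLER_SENTENCES = (
    "Genome-wide significance was assessed at the conventional threshold.",
    "Quality control filters were applied to the genotype data.",
    "Imputation was performed against a standard reference panel.",
    "Association tests used an additive genetic model.",
    "Principal components were included to adjust for stratification.",
    "The strongest signal mapped to a previously reported locus.",
    "Functional annotation suggested a plausible regulatory mechanism.",
    "Summary statistics are available from the authors on request.",
)


def default_sample_lexicon() -> RuleLexicon:
    return RuleLexicon(frozenset(t.casefold() for t in SAMPLE_DESCRIPTION_TERMS),
                       "sample_description")


def default_initial_cues() -> RuleLexicon:
    return RuleLexicon(frozenset(t.casefold() for t in INITIAL_CUE_TERMS),
                       "initial_cue")


def default_replication_cues() -> RuleLexicon:
    return RuleLexicon(frozenset(t.casefold() for t in REPLICATION_CUE_TERMS),
                       "replication_cue")


def phenotype_dictionary() -> TermDictionary:
    entries = {}
    for canonical, synonyms in PHENOTYPES.items():
        entries[canonical.casefold()] = canonical
        for s in synonyms:
            entries[s.casefold()] = canonical
    return TermDictionary(entries=entries, name="phenotypes")


def ethnicity_dictionary() -> TermDictionary:
    entries = {}
    for group, surfaces in ETHNICITY_GROUPS.items():
        for s in surfaces:
            entries[s.casefold()] = group
    return TermDictionary(entries=entries, name="ethnicities")


# ---------------------------------------------------------------------------
# Committee matrix simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommitteeSimConfig:
    """Ground-truth conditions for simulated committee voting: I passages,
    J conditionally independent weak classifiers, each flipping the true
    label with its own error rate (< 0.5: better than chance)."""

    I: int = 1000
    J: int = 7
    prior_pos: float = 0.4
    error_rates: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.33, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I < 1 or self.J < 1:
            raise ConfigError("I and J must be positive")
        if not (0.0 < self.prior_pos < 1.0):
            raise ConfigError("prior_pos must lie in (0, 1)")
        if len(self.error_rates) != self.J:
            raise ConfigError("need one error rate per classifier")
        if any(not (0.0 <= e < 0.5) for e in self.error_rates):
            raise ConfigError("error rates must lie in [0, 0.5)")


def gen_committee_matrix(
    cfg: CommitteeSimConfig,
) -> tuple[CommitteeMatrix, np.ndarray, np.ndarray]:
    """Draw (matrix, true_labels, true_error_rates) from the config."""
    rng = np.random.default_rng(cfg.seed)
    labels = (rng.random(cfg.I) < cfg.prior_pos).astype(int)
    errors = np.asarray(cfg.error_rates, dtype=float)
    flips = rng.random((cfg.I, cfg.J)) < errors[None, :]
    M = np.where(flips, 1 - labels[:, None], labels[:, None]).astype(np.int8)
    matrix = CommitteeMatrix(
        M=M,
        passage_ids=[f"p{i}" for i in range(cfg.I)],
        classifier_ids=[f"clf_{j}" for j in range(cfg.J)],
    )
    return matrix, labels, errors


# ---------------------------------------------------------------------------
# Corpus simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSimConfig:
    """Conditions for miniature corpora with planted structure.

    ``target_in_title_prob`` is the chance a gold phenotype is planted in
    the title (otherwise it appears in the abstract); ``synonym_swap_prob``
    and ``typo_prob`` corrupt the curated term relative to the planted
    text; ``label_noise`` is the per-tuple chance that a curated
    stage/ethnicity tuple names a bystander group instead of the true
    sample; ``stage_cue_prob`` is the chance a sample sentence states its
    stage explicitly.
    """

    n_docs: int = 200
    n_entities: int = 4
    mentions_per_doc: tuple[int, int] = (1, 3)
    target_in_title_prob: float = 0.9
    synonym_swap_prob: float = 0.3
    typo_prob: float = 0.1
    label_noise: float = 0.0
    stage_cue_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_in_title_prob", "synonym_swap_prob", "typo_prob",
                     "label_noise", "stage_cue_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_docs < 1:
            raise ConfigError("n_docs must be positive")


def _typo(term: str, rng: np.random.Generator) -> str:
    """Single-character substitution or deletion."""
    letters = [i for i, ch in enumerate(term) if ch.isalpha()]
    if not letters:
        return term
    i = int(rng.choice(letters))
    if rng.random() < 0.5 and len(term) > 3:
        return term[:i] + term[i + 1:]
    repl = chr(ord("a") + int(rng.integers(26)))
    return term[:i] + repl + term[i + 1:]


def _fillers(rng: np.random.Generator, n: int) -> list[str]:
    return [str(rng.choice(_FILLER_SENTENCES)) for _ in range(n)]


def gen_task1_corpus(
    cfg: CorpusSimConfig,
) -> tuple[list[Article], list[CuratedRecord], TermDictionary, dict[str, frozenset[str]]]:
    """Articles with planted target phenotypes plus body distractors.

    Each document gets one gold phenotype, two with probability 0.5
    (matching curated databases where papers average ~1.5 target
    phenotypes). The curated term is the planted canonical, a synonym, or
    a typo variant per the config probabilities. Returns (articles,
    curated records, dictionary, gold canonicals per document).
    """
    rng = np.random.default_rng(cfg.seed)
    dictionary = phenotype_dictionary()
    names = sorted(PHENOTYPES)
    articles, records, gold = [], [], {}
    for d in range(cfg.n_docs):
        doc_id = f"T1D{d:04d}"
        n_gold = 2 if rng.random() < 0.5 else 1
        chosen = [names[i] for i in rng.choice(len(names), size=n_gold,
                                               replace=False)]
        distractors = [names[i] for i in rng.choice(len(names), size=3,
                                                    replace=False)
                       if names[i] not in chosen][:2 + int(rng.integers(0, 2))]

        primary = chosen[0]
        in_title = rng.random() < cfg.target_in_title_prob
        title = (f"Genome-wide association study of {primary}"
                 if in_title else "A large-scale genome-wide association scan")
        abstract_bits = [
            f"We conducted a genome-wide association study of {primary} "
            f"in a large cohort."]
        for extra in chosen[1:]:
            abstract_bits.append(
                f"Associated traits including {extra} were also examined.")
        abstract = " ".join(abstract_bits)

        results = []
        for name in chosen:
            surfaces = [name] + PHENOTYPES[name]
            for _ in range(int(rng.integers(*cfg.mentions_per_doc)) + 1):
                surface = (str(rng.choice(surfaces[1:]))
                           if (len(surfaces) > 1 and rng.random() < 0.3)
                           else name)
                results.append(f"Variants showed genome-wide significant "
                               f"association with {surface}.")
        for name in distractors:
            for _ in range(int(rng.integers(1, 3))):
                results.append(f"Previous studies have linked nearby loci "
                               f"to {name}.")
        order = rng.permutation(len(results))
        results = [results[i] for i in order]

        article = Article(
            doc_id=doc_id, title=title, abstract=abstract,
            sections=[
                ("Methods", _fillers(rng, 2)),
                ("Results", [" ".join(results + _fillers(rng, 1))]),
                ("Discussion", _fillers(rng, 2)),
            ])
        curated_terms = []
        for name in chosen:
            u = rng.random()
            if u < cfg.synonym_swap_prob and PHENOTYPES[name]:
                curated_terms.append(str(rng.choice(PHENOTYPES[name])))
            elif u < cfg.synonym_swap_prob + cfg.typo_prob:
                curated_terms.append(_typo(name, rng))
            else:
                curated_terms.append(name)
        articles.append(article)
        records.append(CuratedRecord(doc_id, "phenotype",
                                     phenotype_terms=curated_terms))
        gold[doc_id] = frozenset(chosen)
    return articles, records, dictionary, gold


_SAMPLE_WORDS = ("participants", "individuals", "subjects")
_RECRUIT_WORDS = ("recruited", "enrolled", "genotyped")


def _sample_sentence(surface: str, stage: str, with_cue: bool,
                     rng: np.random.Generator) -> str:
    n = int(rng.integers(5, 95)) * 100
    sample_word = str(rng.choice(_SAMPLE_WORDS))
    recruit_word = str(rng.choice(_RECRUIT_WORDS))
    if with_cue:
        cues = INITIAL_CUE_TERMS if stage == "initial" else REPLICATION_CUE_TERMS
        cue = str(rng.choice(cues))
        phase = cue if cue.endswith("stage") else f"{cue} stage"
        return (f"A total of {n} {surface} {sample_word} were {recruit_word} "
                f"in the {phase} of the study.")
    return (f"A total of {n} {surface} {sample_word} were {recruit_word} "
            f"for this study.")


def gen_task2_corpus(
    cfg: CorpusSimConfig,
) -> tuple[list[Article], list[CuratedRecord], TermDictionary,
           dict[str, frozenset[tuple[str, str]]]]:
    """Articles pairing ethnicity mentions with stage cues, plus bystanders.

    Per document: one or two ethnicity groups in the initial stage, a
    replication group with probability 0.6; each true (stage, ethnicity)
    tuple is supported by one or two sample-description sentences (with a
    stage cue word with probability ``stage_cue_prob``), sometimes echoed
    by an unlinked mention; one or two bystander groups appear only in
    background sentences. With probability ``label_noise`` a curated
    tuple's ethnicity is swapped for a bystander group, corrupting the
    weak labels on both sides. The evaluation gold (returned separately)
    stays clean. Dictionary coverage is complete: every gold tuple has at
    least one tagged, in-text mention.
    """
    rng = np.random.default_rng(cfg.seed)
    dictionary = ethnicity_dictionary()
    groups = sorted(ETHNICITY_GROUPS)
    articles, records, gold = [], [], {}
    for d in range(cfg.n_docs):
        doc_id = f"T2D{d:04d}"
        perm = [groups[i] for i in rng.permutation(len(groups))]
        n_initial = 2 if rng.random() < 0.4 else 1
        initial_groups = perm[:n_initial]
        pos = n_initial
        tuples: set[tuple[str, str]] = {("initial", g) for g in initial_groups}
        if rng.random() < 0.6:
            if rng.random() < 0.5:
                tuples.add(("replication", initial_groups[0]))
            else:
                tuples.add(("replication", perm[pos]))
                pos += 1
        bystanders = perm[pos:pos + 1 + int(rng.integers(0, 2))]

        methods, results = [], []
        for stage, group in sorted(tuples):
            surfaces = ETHNICITY_GROUPS[group]
            for _ in range(1 + int(rng.integers(0, 2))):
                surface = str(rng.choice(surfaces))
                methods.append(_sample_sentence(
                    surface, stage, rng.random() < cfg.stage_cue_prob, rng))
            if rng.random() < 0.5:
                surface = str(rng.choice(surfaces))
                results.append(f"Effect sizes were consistent across the "
                               f"{surface} data.")
        for group in bystanders:
            surface = str(rng.choice(ETHNICITY_GROUPS[group]))
            results.append(f"Earlier reports described similar loci in "
                           f"{surface} groups.")
        methods.extend(_fillers(rng, 1))
        results.extend(_fillers(rng, 2))
        rng.shuffle(methods)
        rng.shuffle(results)

        articles.append(Article(
            doc_id=doc_id,
            title="A genome-wide association study of a complex trait",
            abstract="We report genome-wide association results across "
                     "several ancestry groups.",
            sections=[("Methods", [" ".join(methods)]),
                      ("Results", [" ".join(results)]),
                      ("Discussion", _fillers(rng, 2))]))

        curated = set()
        for stage, group in sorted(tuples):
            if bystanders and rng.random() < cfg.label_noise:
                curated.add((stage, str(rng.choice(bystanders))))
            else:
                curated.add((stage, group))
        records.append(CuratedRecord(doc_id, "stage_ethnicity",
                                     tuples=frozenset(curated)))
        gold[doc_id] = frozenset(tuples)
    return articles, records, dictionary, gold


# ---------------------------------------------------------------------------
# Corpus serialisation (exercises the real readers/writers)
# ---------------------------------------------------------------------------

def save_corpus(
    out_dir: str | Path,
    articles: list[Article],
    records: list[CuratedRecord],
    dictionary: TermDictionary,
    gold=None,
) -> None:
    """Write a generated corpus in the package's standard file formats."""
    out = Path(out_dir)
    (out / "articles").mkdir(parents=True, exist_ok=True)
    for article in articles:
        write_article(article, out / "articles" / f"{article.doc_id}.xml")
    write_curated_table(records, out / "curated.tsv")
    dump_dictionary(dictionary, out / "dictionary.tsv")
    dump_lexicon(default_sample_lexicon(), out / "sample_lexicon.txt")
    dump_lexicon(default_initial_cues(), out / "initial_cues.txt")
    dump_lexicon(default_replication_cues(), out / "replication_cues.txt")
    if gold is not None:
        with open(out / "gold.tsv", "w", encoding="utf-8") as fh:
            first = next(iter(gold.values()), frozenset())
            if first and isinstance(next(iter(first), None), tuple):
                fh.write("DOC_ID\tSTAGE\tETHNICITY\n")
                for doc in sorted(gold):
                    for stage, eth in sorted(gold[doc]):
                        fh.write(f"{doc}\t{stage}\t{eth}\n")
            else:
                fh.write("DOC_ID\tDISEASETRAIT\n")
                for doc in sorted(gold):
                    for term in sorted(gold[doc]):
                        fh.write(f"{doc}\t{term}\n")


__all__ = [
    "CommitteeSimConfig", "CorpusSimConfig", "gen_committee_matrix",
    "gen_task1_corpus", "gen_task2_corpus", "save_corpus",
    "phenotype_dictionary", "ethnicity_dictionary",
    "default_sample_lexicon", "default_initial_cues",
    "default_replication_cues", "PHENOTYPES", "ETHNICITY_GROUPS",
    "SAMPLE_DESCRIPTION_TERMS", "INITIAL_CUE_TERMS", "REPLICATION_CUE_TERMS",
]
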