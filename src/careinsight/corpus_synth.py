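"""Synthetic multi-task corpus generator with planted signal phrases.

Real care-need assessments are private, so downstream stages are exercised on
generated corpora that emulate their structure: long filler documents into
which task-specific signal phrases are planted at known positions.  Each
module label is a monotone function of the planted signal mass for that
module, and the overall care-need label is the weighted, discretized
aggregate of the module labels — mirroring how the assessment instrument sums
weighted module scores into a final care grade.

The :class:`PlantedPhraseRegistry` records every planting event, providing
ground truth for phrase-recovery and faithfulness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CARE_NEED, MODULE_TASKS, Corpus, Document, TaskLabels

_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyzäöüß"

# a few high-frequency function words mixed into the filler stream so that
# stop-word exclusion in phrase construction is exercised
_FILLER_STOPWORDS = (
    "der die das und ist mit bei nicht auch eine im von wird kann sich".split()
)


@dataclass(frozen=True)
class SignalPhrase:
    """A 1-3-word phrase planted into documents of its owning task(s).

    ``target_frequency`` is the expected number of documents containing the
    phrase; ``strength`` scales its contribution to the module level.
    """

    phrase: str
    target_frequency: int
    strength: float = 1.0

    @property
    def words(self) -> tuple[str, ...]:
        ws = tuple(self.phrase.split())
        return ws

    def __post_init__(self):
        n = len(self.phrase.split())
        if not 1 <= n <= 3:
            raise ValueError(f"signal phrase must have 1-3 words: {self.phrase!r}")
        if self.target_frequency < 1:
            raise ValueError("target_frequency must be >= 1")


@dataclass
class GeneratorConfig:
    n_docs: int = 3000
    mean_length: float = 200.0
    sd_length: float = 50.0
    filler_vocab_size: int = 2000
    zipf_exponent: float = 1.1
    stopword_rate: float = 0.25
    signal_phrases: dict = field(default_factory=dict)  # task -> [SignalPhrase]
    shared_phrases: list = field(default_factory=list)  # [SignalPhrase], all modules
    shared_strength: float = 0.5
    typo_rate: float = 0.02
    level_alpha: float = 1.0
    #: each document draws one global severity latent plus one per-module
    #: latent (both gamma with mean 1); the planting probability of a module's
    #: phrases scales with ``mix·global + (1-mix)·module``.  The global
    #: component correlates impairment across areas of life (as in real
    #: assessments, where severe cases score high in several modules), the
    #: module component keeps tasks separable.
    severity_mix: float = 0.5
    severity_shape_global: float = 0.5
    severity_shape_module: float = 0.8
    #: minimum relative document position for phrase insertion (0 = anywhere);
    #: e.g. 0.5 confines all signal to the second half of each document,
    #: which makes truncating classifiers blind to it
    signal_position: float = 0.0
    module_weights: tuple = (0.10, 0.075, 0.075, 0.40, 0.20, 0.15)
    label_flip_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.module_weights) - 1.0) > 1e-9:
            raise ValueError("module_weights must sum to 1")
        if len(self.module_weights) != len(MODULE_TASKS):
            raise ValueError("need one weight per module task")
        longest = 1
        for task in MODULE_TASKS:
            phrases = self.signal_phrases.get(task, [])
            if not phrases:
                raise ValueError(f"task {task!r} has no exclusive signal phrase")
            longest = max(longest, max(len(p.words) for p in phrases))
        if self.mean_length < longest:
            raise ValueError("mean_length smaller than the longest signal phrase")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ValueError("typo_rate must be in [0, 1]")


@dataclass
class PlantingEvent:
    doc_id: str
    position: int  # word index of the phrase start in the final document
    realized_words: tuple  # words as planted (possibly typo-corrupted)
    copies_key: int = 0


@dataclass
class PlantedPhraseRegistry:
    """Ground truth: which phrases were planted where, and for which tasks."""

    owners: dict = field(default_factory=dict)  # phrase -> tuple(task ids)
    events: dict = field(default_factory=dict)  # phrase -> [PlantingEvent]
    typo_log: list = field(default_factory=list)  # (doc_id, original, corrupted)

    def record(self, phrase: str, tasks, event: PlantingEvent) -> None:
        self.owners.setdefault(phrase, tuple(tasks))
        self.events.setdefault(phrase, []).append(event)

    def docs_for(self, phrase: str) -> set:
        return {e.doc_id for e in self.events.get(phrase, [])}

    def exclusive_phrases(self, task: str) -> list:
        return [p for p, owners in self.owners.items() if owners == (task,)]

    def shared_phrases(self) -> list:
        return [p for p, owners in self.owners.items() if len(owners) > 1]

    def signal_words(self, task: str) -> set:
        """Uncorrupted words of the task's exclusive phrases.

        For the derived overall care-need task this is the union over all
        modules: every module signal is by construction a care-need signal.
        """
        if task == CARE_NEED:
            out = set()
            for m in MODULE_TASKS:
                out |= self.signal_words(m)
            return out
        words = set()
        for p in self.exclusive_phrases(task):
            words.update(p.split())
        return words


def inject_typos(words, typo_rate: float, seed: int):
    """Corrupt each word independently with probability ``typo_rate``.

    A corruption is a single character deletion or substitution (edit
    distance 1).  Rate 0 is the identity.
    """
    rng = np.random.default_rng(seed)
    return [_maybe_typo(w, typo_rate, rng)[0] for w in words]


def _maybe_typo(word: str, rate: float, rng) -> tuple[str, bool]:
    if rate <= 0 or rng.random() >= rate:
        return word, False
    pos = int(rng.integers(0, len(word)))
    if len(word) > 1 and rng.random() < 0.5:
        return word[:pos] + word[pos + 1 :], True
    choices = [c for c in _TYPO_ALPHABET if c != word[pos]]
    sub = choices[int(rng.integers(0, len(choices)))]
    return word[:pos] + sub + word[pos + 1 :], True


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-condition defaults: 3,000 long documents, 7 correlated tasks,
    per-module exclusive phrases spanning common to singleton frequencies,
    plus shared high-entropy phrases planted across all modules.

    Phrase target frequencies scale with ``n_docs`` (fractions 10%, 5%, 2.7%,
    1.3%, 0.33% of the corpus plus one singleton), so the default 3,000-doc
    corpus plants them in about 300/150/80/40/10/1 documents respectively.
    """
    n_docs = int(overrides.get("n_docs", GeneratorConfig.n_docs))
    fracs = (
        0.10, 0.09, 0.08, 0.07, 0.06, 0.05, 0.04, 0.035, 0.03,
        0.025, 0.02, 0.015, 0.012, 0.01, 0.008, 0.005, 1 / 300.0,
    )
    freqs = tuple(max(1, round(f * n_docs)) for f in fracs) + (1,)

    def phrases(words):
        return [SignalPhrase(p, f) for p, f in zip(words, freqs)]

    signal = {
        "m1_mobility": phrases(
            ["rollator", "treppensteigen", "gehstrecke verkürzt",
             "transfer bett rollstuhl", "sturzgefahr", "gangbild unsicher",
             "umsetzen mit hilfe", "lagerung nachts", "gehwagen benutzt",
             "treppenlift vorhanden", "haltegriffe bad", "balance gestört",
             "aufstehen schwerfällig", "rollstuhl angewiesen", "bettkante sitzen",
             "sturz ereignet", "gehhilfe erforderlich", "positionswechsel unterstützt"]
        ),
        "m2_cognitive": phrases(
            ["kurzzeitgedächtnis lückenhaft", "desorientiert", "wortfindung gestört",
             "demenz", "merkfähigkeit eingeschränkt", "aphasie",
             "orientierung zeitlich fehlend", "einfache sachverhalte",
             "gespräch inhaltlich", "erinnerungslücken", "ansprache reagiert verzögert",
             "konzentration reduziert", "langzeitgedächtnis erhalten", "personen erkennen",
             "mehrschrittige aufforderungen", "risiken einschätzen",
             "gedächtnisstörung ausgeprägt", "sachverhalte mitteilen"]
        ),
        "m3_behavioral": phrases(
            ["nächtliche unruhe", "abwehrverhalten", "weglauftendenz", "aggressiv",
             "stimmungsschwankungen", "rufen nachts", "ängste ausgeprägt",
             "antriebslosigkeit", "wahnvorstellungen", "verkennt situationen",
             "motorische unruhe", "verweigert pflege", "beschimpft pflegende",
             "depressive verstimmung", "sozialer rückzug", "enthemmtes verhalten",
             "halluzinationen", "adressat sorgen"]
        ),
        "m4_selfsuff": phrases(
            ["körperpflege übernommen", "ankleiden unmöglich", "duschen mit hilfe",
             "inkontinenz", "nahrungsaufnahme angereicht", "rasur übernommen",
             "kleidung richten", "verschlüsse öffnen", "mundgerecht zerkleinern",
             "toilettengang begleitet", "waschen oberkörper", "kämmen eingeschränkt",
             "intimhygiene unterstützt", "getränke eingießen", "zahnprothese reinigen",
             "anziehen strümpfe", "essen portioniert", "harndrang verspürt"]
        ),
        "m5_selftherapy": phrases(
            ["medikamente gerichtet", "insulingabe", "kompressionsstrümpfe anziehen",
             "verbandswechsel", "dialyse", "injektion vorbereitet", "blutdruckmessung",
             "arztbesuche begleitet", "sauerstofftherapie", "blutzuckerkontrolle",
             "salbe auftragen", "heimbeatmung", "augentropfen verabreicht",
             "inhalation durchgeführt", "wundversorgung täglich", "physiotherapie verordnet",
             "stoma versorgt", "katheter gepflegt"]
        ),
        "m6_everyday": phrases(
            ["tagesstruktur fehlt", "beschäftigung angeleitet", "hauswirtschaft übernommen",
             "einkaufen begleitet", "waschmaschine bedienen", "telefonkontakt gehalten",
             "zukunftsplanung", "tagespflege besucht", "kontakte pflegen", "zeitung lesen",
             "mahlzeiten planen", "ruhen gestört", "schlafrhythmus verschoben",
             "besuch empfangen", "fernsehen interesse", "hobbys aufgegeben",
             "veranstaltungen besucht", "alltagsgestaltung hilfe"]
        ),
    }
    shared_freq = max(1, round(n_docs / 15))
    shared = [
        SignalPhrase("unterstützung erforderlich", shared_freq),
        SignalPhrase("hilfe notwendig", shared_freq),
    ]
    cfg = GeneratorConfig(signal_phrases=signal, shared_phrases=shared, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, PlantedPhraseRegistry]:
    """Generate a corpus with planted phrases and derived labels.

    Module level = ``min(4, floor(level_alpha * weighted signal count))``;
    care need = the module-weight aggregate of module levels rescaled to 0-5
    and rounded.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    registry = PlantedPhraseRegistry()

    vocab = np.array([f"wort{i:04d}" for i in range(config.filler_vocab_size)])
    ranks = np.arange(1, config.filler_vocab_size + 1, dtype=float)
    zipf_p = ranks ** (-config.zipf_exponent)
    zipf_p /= zipf_p.sum()
    stop_arr = np.array(_FILLER_STOPWORDS)

    documents, labels = [], {}
    for i in range(config.n_docs):
        doc_id = f"doc{i:05d}"
        length = max(10, int(round(rng.normal(config.mean_length, config.sd_length))))
        n_stop = rng.binomial(length, config.stopword_rate)
        filler = list(vocab[rng.choice(config.filler_vocab_size, size=length - n_stop, p=zipf_p)])
        filler += list(stop_arr[rng.integers(0, len(stop_arr), size=n_stop)])
        rng.shuffle(filler)
        units = [[w] for w in filler]

        g = rng.gamma(config.severity_shape_global, 1.0 / config.severity_shape_global)
        severity = {
            m: config.severity_mix * g
            + (1.0 - config.severity_mix)
            * rng.gamma(config.severity_shape_module, 1.0 / config.severity_shape_module)
            for m in MODULE_TASKS
        }
        sev_mean = float(np.mean(list(severity.values())))
        counts = {m: 0.0 for m in MODULE_TASKS}
        plantings = []  # (phrase, owners, realized words)
        for task in MODULE_TASKS:
            for sp in config.signal_phrases[task]:
                if rng.random() < min(1.0, severity[task] * sp.target_frequency / config.n_docs):
                    copies = 1 + int(rng.poisson(0.7))
                    copies = min(copies, 3)
                    counts[task] += copies * sp.strength
                    for _ in range(copies):
                        plantings.append((sp, (task,)))
        for sp in config.shared_phrases:
            if rng.random() < min(1.0, sev_mean * sp.target_frequency / config.n_docs):
                copies = 1 + int(rng.poisson(0.7))
                copies = min(copies, 3)
                for m in MODULE_TASKS:
                    counts[m] += copies * config.shared_strength
                for _ in range(copies):
                    plantings.append((sp, MODULE_TASKS))

        marked = []  # (unit index into `units` content, phrase, owners, realized)
        for sp, owners in plantings:
            realized = []
            for w in sp.words:
                corrupted, was_typo = _maybe_typo(w, config.typo_rate, rng)
                realized.append(corrupted)
                if was_typo:
                    registry.typo_log.append((doc_id, w, corrupted))
            unit = list(realized)
            lo = int(config.signal_position * len(units))
            idx = int(rng.integers(lo, len(units) + 1))
            units.insert(idx, unit)
            marked.append((unit, sp, owners, tuple(realized)))

        words, start_of = [], {}
        for unit in units:
            start_of[id(unit)] = len(words)
            words.extend(unit)
        for unit, sp, owners, realized in marked:
            registry.record(
                sp.phrase, owners,
                PlantingEvent(doc_id=doc_id, position=start_of[id(unit)],
                              realized_words=realized),
            )

        levels = {}
        for m in MODULE_TASKS:
            lvl = min(4, int(np.floor(config.level_alpha * counts[m])))
            if config.label_flip_rate > 0 and rng.random() < config.label_flip_rate:
                lvl = int(rng.integers(0, 5))
            levels[m] = lvl
        agg = sum(w * levels[m] for w, m in zip(config.module_weights, MODULE_TASKS))
        levels[CARE_NEED] = int(np.clip(round(agg * 5.0 / 4.0), 0, 5))

        documents.append(Document(doc_id=doc_id, text=" ".join(words)))
        labels[doc_id] = TaskLabels(levels)

    return Corpus(documents, labels), registry
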