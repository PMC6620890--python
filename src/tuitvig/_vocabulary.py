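"""Word inventories behind the bundled resources and the synthetic generator.

Everything here is a closed, hand-curated Spanish word list.  The same
inventories produce (a) the bundled tagged vocabulary and lexicon files under
``tuitvig/data/`` and (b) the synthetic generator's vocabulary bank, so
every generated word is resolvable by the dictionary tagger and by the
relevant lexicons — the property the recovery tests rely on.

The bundled emotion and polarity lexicons are synthetic stand-ins sized and
shaped like published Spanish sentiment resources, not redistributions of
them: binary-polarity, graded-polarity and emotion term sets are pairwise
disjoint (real lexicons overlap) so corpus-level injection rates stay
exactly attributable to one lexicon each.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

# ---------------------------------------------------------------------------
# Screening keywords (depression-related terms; "/a" marks gender variants)

DEPRESSION_KEYWORDS = [
    "agobiado/a", "agotado/a", "angustiado/a", "ansiedad", "ansioso/a",
    "cansado/a", "decaído", "depresión", "depresivo/a", "deprimido/a",
    "desanimado/a", "desesperado/a", "desmotivado/a", "insomnio", "llorar",
    "nervioso", "preocupado/a", "solo/a", "triste", "vacío/a",
]

DEPR_DERIVATIONS = [
    "depre", "depresión", "depresivo", "depresiva", "deprimido", "deprimida",
]

NEGATIONS = [
    "no", "nada", "nadie", "nunca", "jamás", "ni", "ningún", "ninguno",
    "ninguna", "tampoco", "sin",
]

# 100 most common Spanish function words (top_words filtering + control
# stream matching).
STOPWORDS = [
    "de", "la", "que", "el", "en", "y", "a", "los", "del", "se", "las",
    "por", "un", "para", "con", "no", "una", "su", "al", "lo", "como",
    "más", "pero", "sus", "le", "ya", "o", "este", "sí", "porque", "esta",
    "entre", "cuando", "muy", "sin", "sobre", "también", "me", "hasta",
    "hay", "donde", "quien", "desde", "todo", "nos", "durante", "todos",
    "uno", "les", "ni", "contra", "otros", "ese", "eso", "ante", "ellos",
    "e", "esto", "mí", "antes", "algunos", "qué", "unos", "yo", "otro",
    "otras", "otra", "él", "tanto", "esa", "estos", "mucho", "quienes",
    "nada", "muchos", "cual", "poco", "ella", "estar", "estas", "algunas",
    "algo", "nosotros", "mi", "mis", "tú", "te", "ti", "tu", "tus", "ellas",
    "nosotras", "vosotros", "vosotras", "os", "mío", "mía", "aunque",
    "esos", "esas",
]

# ---------------------------------------------------------------------------
# Gender/number expansion helpers


def expand_o_stem(stem: str) -> list[str]:
    """masc-o stem -> o/a/os/as forms (bonito -> bonita, bonitos, bonitas)."""
    assert stem.endswith("o"), stem
    base = stem[:-1]
    return [stem, base + "a", base + "os", base + "as"]


def expand_invariable(stem: str) -> list[str]:
    """Invariable adjective -> singular + plural (-s after vowel, -es else)."""
    plural = stem + ("s" if stem[-1] in "aeiouáéíóú" else "es")
    return [stem, plural]


def expand_keyword(entry: str) -> list[str]:
    """'agobiado/a' -> ['agobiado', 'agobiada']; plain entries unchanged."""
    if entry.endswith("/a"):
        stem = entry[:-2]
        return [stem, stem[:-1] + "a"]
    return [entry]


# ---------------------------------------------------------------------------
# Emotion lexicon (six basic emotions).  Single-emotion pools feed the
# generator; the few multi-emotion terms exercise multi-label scoring.

EMOTION_TERMS: dict[str, list[str]] = {
    "happiness": [
        "alegría", "felicidad", "euforia", "gozo", "júbilo",
        "feliz", "felices", "alegre", "alegres", "risueño", "risueña",
        "contento", "contenta", "contentos", "contentas",
        "dichoso", "dichosa", "encantado", "encantada",
        "ilusionado", "ilusionada", "reír", "sonreír",
    ],
    "sadness": [
        "tristeza", "pena", "melancolía", "luto", "lágrima", "lágrimas",
        "triste", "tristes", "apenado", "apenada", "abatido", "abatida",
        "desconsolado", "desconsolada", "deprimido", "deprimida",
        "sollozar",
    ],
    "anger": [
        "enojo", "rabia", "ira", "furia", "rencor", "odio",
        "enfadado", "enfadada", "furioso", "furiosa",
        "indignado", "indignada", "cabreado", "cabreada",
        "irritado", "irritada", "odiar",
    ],
    "fear": [
        "miedo", "terror", "susto", "pánico", "temor", "espanto",
        "asustado", "asustada", "temeroso", "temerosa",
        "aterrado", "aterrada", "temer",
    ],
    "disgust": [
        "asco", "repulsión", "náusea", "repugnancia",
        "asqueado", "asqueada", "asqueroso", "asquerosa",
        "repugnante", "repugnantes", "aborrecer",
    ],
    "surprise": [
        "sorpresa", "asombro",
        "sorprendido", "sorprendida", "asombrado", "asombrada",
        "atónito", "atónita", "impactado", "impactada",
        "inesperado", "inesperada",
    ],
}

#: term -> multiple emotions (kept out of the generator pools).
MULTI_EMOTION_TERMS: dict[str, list[str]] = {
    "angustia": ["sadness", "fear"],
    "agridulce": ["happiness", "sadness"],
}

# ---------------------------------------------------------------------------
# Binary polarity lexicon (sign only)

_BINARY_POS_O = [
    "bueno", "estupendo", "maravilloso", "bonito", "precioso", "divertido",
    "afortunado", "generoso", "honesto", "limpio", "sano", "exitoso",
    "cariñoso", "amoroso", "luminoso", "espléndido", "fabuloso", "perfecto",
]
_BINARY_POS_INV = [
    "admirable", "excelente", "genial", "brillante", "amable", "formidable",
    "radiante",
]
_BINARY_NEG_O = [
    "malo", "feo", "pésimo", "desastroso", "sucio", "odioso", "penoso",
    "nefasto", "dañino", "tóxico", "amargo", "funesto",
]
_BINARY_NEG_INV = [
    "horrible", "cruel", "lamentable", "deplorable", "vil", "infame",
    "ruin", "miserable",
]


def _expand_all(o_stems: list[str], inv_stems: list[str]) -> list[str]:
    out: list[str] = []
    for s in o_stems:
        out.extend(expand_o_stem(s))
    for s in inv_stems:
        out.extend(expand_invariable(s))
    return out


BINARY_POSITIVE = _expand_all(_BINARY_POS_O, _BINARY_POS_INV)
BINARY_NEGATIVE = _expand_all(_BINARY_NEG_O, _BINARY_NEG_INV)

# ---------------------------------------------------------------------------
# Graded polarity lexicon (real values in [-1, 1]; ±0.8 strong, ±0.4 mild)

_GRADED_STEMS: list[tuple[str, bool, float]] = [  # (stem, is_o_stem, value)
    ("magnífico", True, 0.8), ("fantástico", True, 0.8),
    ("extraordinario", True, 0.8), ("glorioso", True, 0.8),
    ("sublime", False, 0.8), ("insuperable", False, 0.8),
    ("majestuoso", True, 0.8),
    ("agradable", False, 0.4), ("decente", False, 0.4),
    ("aceptable", False, 0.4), ("interesante", False, 0.4),
    ("razonable", False, 0.4), ("correcto", True, 0.4),
    ("entretenido", True, 0.4),
    ("espantoso", True, -0.8), ("catastrófico", True, -0.8),
    ("pavoroso", True, -0.8), ("horrendo", True, -0.8),
    ("atroz", False, -0.8), ("abominable", False, -0.8),
    ("aberrante", False, -0.8),
    ("molesto", True, -0.4), ("aburrido", True, -0.4),
    ("flojo", True, -0.4), ("insulso", True, -0.4),
    ("soso", True, -0.4), ("mediocre", False, -0.4),
    ("torpe", False, -0.4),
]


def _graded_entries() -> dict[str, float]:
    out: dict[str, float] = {}
    for stem, is_o, value in _GRADED_STEMS:
        forms = expand_o_stem(stem) if is_o else expand_invariable(stem)
        for f in forms:
            out[f] = value
    return out


GRADED_ENTRIES = _graded_entries()

# ---------------------------------------------------------------------------
# Neutral (lexicon-free) inventories, by POS

NEUTRAL_NOUNS = [
    "casa", "perro", "gato", "libro", "mesa", "ciudad", "calle", "coche",
    "trabajo", "escuela", "comida", "agua", "cielo", "tierra", "fuego",
    "música", "película", "partido", "equipo", "juego", "foto", "playa",
    "montaña", "río", "árbol", "flor", "papel", "puerta", "ventana",
    "reloj", "teléfono", "camino", "viaje", "historia", "noche", "vida",
    "tiempo", "gente", "mundo", "amigo", "amiga", "familia", "semana",
    "mes", "año", "día", "cosa", "mano", "cabeza", "palabra",
]
NEUTRAL_VERBS = [
    "es", "está", "están", "era", "fue", "ir", "voy", "va", "vamos",
    "hacer", "hago", "hace", "ver", "veo", "ve", "tener", "tengo", "tiene",
    "decir", "digo", "dice", "poder", "puedo", "puede", "querer", "quiero",
    "quiere", "comer", "come", "vivir", "vive", "hablar", "habla", "jugar",
    "juega", "leer", "lee", "escribir", "escribe", "pensar", "pienso",
    "piensa", "siento", "siente", "trabajar", "trabaja", "estudiar",
    "estudia", "caminar", "camina", "cantar", "canta", "dormir", "duerme",
]
NEUTRAL_ADJECTIVES = [
    "grande", "grandes", "pequeño", "pequeña", "nuevo", "nueva", "viejo",
    "vieja", "alto", "alta", "joven", "rojo", "roja", "azul", "verde",
    "blanco", "blanca", "negro", "negra", "rápido", "rápida", "lento",
    "lenta", "fuerte", "caliente", "frío", "fría", "largo", "larga",
    "corto", "corta",
]
NEUTRAL_ADVERBS = [
    "hoy", "ahora", "siempre", "ayer", "mañana", "aquí", "allí", "bien",
    "luego", "después", "entonces", "cerca", "lejos", "pronto", "tarde",
    "así", "además", "quizás", "casi", "bastante", "demasiado", "también",
    "todavía", "aún",
]
NEGATION_ADVERBS = ["no", "nunca", "jamás", "tampoco"]

DETERMINERS = [
    "el", "un", "una", "unos", "unas", "este", "esta", "estos", "estas",
    "ese", "esa", "esos", "esas", "aquel", "aquella", "mi", "mis", "tu",
    "tus", "su", "sus", "cada", "otro", "otra", "otros", "otras",
]
NEGATION_DETERMINERS = ["ningún"]

ADPOSITIONS = [
    "de", "en", "a", "por", "para", "con", "desde", "hasta", "entre",
    "sobre", "tras", "durante", "hacia", "según", "contra", "bajo",
]
NEGATION_ADPOSITIONS = ["sin"]

CONJUNCTIONS = ["y", "o", "pero", "porque", "aunque", "pues", "mientras",
                "si", "e", "u", "que"]
NEGATION_CONJUNCTIONS = ["ni"]

#: Personal pronouns by person/number class; generator draws by class.
PERSONAL_PRONOUNS: dict[str, list[str]] = {
    "1S": ["yo", "me", "mí", "conmigo"],
    "1P": ["nosotros", "nosotras", "nos"],
    "2S": ["tú", "te", "ti", "vos", "usted"],
    "2P": ["vosotros", "vosotras", "os", "ustedes"],
    "3S": ["él", "ella", "ello", "lo", "la", "le", "se"],
    "3P": ["ellos", "ellas", "los", "las", "les"],
}
#: Pronouns without a person/number class (indefinites, demonstratives).
OTHER_PRONOUNS = ["alguien", "algo", "esto", "eso", "aquello"]
NEGATION_PRONOUNS = ["nada", "nadie", "ninguno", "ninguna"]

# Keyword surface forms by POS (Box-style screening list, expanded)
KEYWORD_ADJECTIVES = sorted(
    {
        form
        for kw in DEPRESSION_KEYWORDS
        for form in expand_keyword(kw)
        if kw not in ("ansiedad", "depresión", "insomnio", "llorar")
    }
)
KEYWORD_NOUNS = ["ansiedad", "depresión", "insomnio"]
KEYWORD_VERBS = ["llorar"]

# ---------------------------------------------------------------------------
# Full POS inventories (must be pairwise disjoint)

_EMOTION_NOUN_SET = {
    "alegría", "felicidad", "euforia", "gozo", "júbilo", "tristeza",
    "pena", "melancolía", "luto", "lágrima", "lágrimas", "enojo", "rabia",
    "ira", "furia", "rencor", "odio", "miedo", "terror", "susto",
    "pánico", "temor", "espanto", "asco", "repulsión", "náusea",
    "repugnancia", "sorpresa", "asombro", "angustia",
}
_EMOTION_VERB_SET = {"reír", "sonreír", "sollozar", "odiar", "temer",
                     "aborrecer"}


def _emotion_forms() -> list[str]:
    forms = set(MULTI_EMOTION_TERMS)
    for terms in EMOTION_TERMS.values():
        forms.update(terms)
    return sorted(forms)


def pos_inventories() -> dict[str, list[str]]:
    """All known word forms per POS category (disjoint by construction)."""
    emo_forms = set(_emotion_forms())
    emo_nouns = sorted(emo_forms & _EMOTION_NOUN_SET)
    emo_verbs = sorted(emo_forms & _EMOTION_VERB_SET)
    emo_adjs = sorted(emo_forms - _EMOTION_NOUN_SET - _EMOTION_VERB_SET)
    inv = {
        "noun": sorted(set(NEUTRAL_NOUNS + KEYWORD_NOUNS + emo_nouns)),
        "verb": sorted(set(NEUTRAL_VERBS + KEYWORD_VERBS + emo_verbs)),
        "pronoun": sorted(
            set(
                [w for forms in PERSONAL_PRONOUNS.values() for w in forms]
                + OTHER_PRONOUNS
                + NEGATION_PRONOUNS
            )
        ),
        "adjective": sorted(
            set(
                NEUTRAL_ADJECTIVES
                + KEYWORD_ADJECTIVES
                + emo_adjs
                + BINARY_POSITIVE
                + BINARY_NEGATIVE
                + list(GRADED_ENTRIES)
            )
        ),
        "determiner": sorted(set(DETERMINERS + NEGATION_DETERMINERS)),
        "adverb": sorted(set(NEUTRAL_ADVERBS + NEGATION_ADVERBS)),
        "adposition": sorted(set(ADPOSITIONS + NEGATION_ADPOSITIONS)),
        "conjunction": sorted(set(CONJUNCTIONS + NEGATION_CONJUNCTIONS)),
    }
    return inv


def pronoun_person_table() -> dict[str, str]:
    return {
        w: person for person, forms in PERSONAL_PRONOUNS.items() for w in forms
    }


# ---------------------------------------------------------------------------
# Bundled file generation (data/ is generated from these inventories)


def emotion_lexicon_rows() -> list[tuple[str, str]]:
    rows = [
        (term, emo)
        for emo, terms in EMOTION_TERMS.items()
        for term in terms
    ]
    rows += [
        (term, emo)
        for term, emos in MULTI_EMOTION_TERMS.items()
        for emo in emos
    ]
    return sorted(rows)


def binary_lexicon_rows() -> list[tuple[str, int]]:
    return sorted(
        [(t, 1) for t in BINARY_POSITIVE] + [(t, -1) for t in BINARY_NEGATIVE]
    )


def graded_lexicon_rows() -> list[tuple[str, float]]:
    return sorted(GRADED_ENTRIES.items())


def tagged_vocabulary_rows() -> list[tuple[str, str, str]]:
    person = pronoun_person_table()
    rows = [
        (word, pos, person.get(word, ""))
        for pos, inventory in pos_inventories().items()
        for word in inventory
    ]
    return sorted(rows)


def write_bundled_data(out_dir: str | Path) -> None:
    """Regenerate every file under ``tuitvig/data/`` from the inventories."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def lines(path: str, rows) -> None:
        (out / path).write_text("\n".join(rows) + "\n", encoding="utf-8")

    lines("depression_keywords.txt", DEPRESSION_KEYWORDS)
    lines("depr_derivations.txt", DEPR_DERIVATIONS)
    lines("negations.txt", NEGATIONS)
    lines("stopwords_es.txt", STOPWORDS)
    lines("emotion_lexicon.tsv", [f"{t}\t{e}" for t, e in emotion_lexicon_rows()])
    lines("polarity_binary.tsv", [f"{t}\t{v:+d}" for t, v in binary_lexicon_rows()])
    lines("polarity_graded.tsv", [f"{t}\t{v:+.2f}" for t, v in graded_lexicon_rows()])
    lines(
        "tagged_vocabulary.tsv",
        [f"{w}\t{p}\t{per}".rstrip("\t") for w, p, per in tagged_vocabulary_rows()],
    )


def data_path(name: str) -> Path:
    """Path to a bundled resource file."""
    return Path(str(resources.files("tuitvig").joinpath("data", name)))
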