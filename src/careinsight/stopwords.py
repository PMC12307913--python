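"""Default German stop-word list.

A compact list of high-frequency German function words used when excluding
stop words from n-gram phrases.  Users can supply their own list (one word per
line) wherever a ``stop_words`` argument is accepted.
"""

GERMAN_STOP_WORDS = frozenset(
    """
    aber alle allem allen aller alles als also am an andere anderen anderer
    anderes auch auf aus bei beim bin bis bist da damit dann das dass dem den
    denn der des dessen die dies diese diesem diesen dieser dieses doch dort
    du durch ein eine einem einen einer eines er es etwas für gegen hab habe
    haben hat hatte hatten hier hin hinter ich ihm ihn ihnen ihr ihre ihrem
    ihren ihrer ihres im in ins ist ja jede jedem jeden jeder jedes kann kein
    keine keinem keinen keiner keines können könnte man mehr mein meine mich
    mir mit muss musste nach nicht nichts noch nun nur ob oder ohne sehr sein
    seine seinem seinen seiner seines selbst sich sie sind so sondern sonst
    über um und uns unser unter vom von vor war waren was weil weiter wenn
    werden wie wieder wir wird wo zu zum zur zwar zwischen
    """.split()
)


def load_stop_words(path=None) -> frozenset:
    """Load a stop-word list from ``path`` (one word per line), or the default."""
    if path is None:
        return GERMAN_STOP_WORDS
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())
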