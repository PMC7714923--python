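"""Run the full study pipeline on a synthetic geometric corpus.

Generates a small corpus of languages whose segment counts are iid geometric
draws, then runs every stage — four families fitted with and without an
estimated x_min, bootstrap plausibility for each fit, pairwise Vuong
comparisons with Bonferroni correction — and prints the summary tables.
"""

from phonotail import CorpusConfig, StudyConfig, TailModel, generate_corpus, run_study, summarize

corpus = generate_corpus(CorpusConfig(
    model=TailModel("exponential", (0.3,), 1), n_languages=8, seed=20,
))
report = run_study(corpus, StudyConfig(n_reps=200, seed=9))
blocks, text = summarize(report)
print(text)
print("Expected pattern: the geometric (exponential) family is plausible for")
print("most languages even without a cutoff, while the no-cutoff power law and")
print("the Poisson are broadly rejected; adding an estimated x_min rescues the")
print("power law on the most-frequent subset of each inventory.")
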