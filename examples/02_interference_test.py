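"""Test whether crossover interference differs between two conditions.

Complete interference limits each chromosome pair to one designated
crossover site; a nucleus showing two foci on a single chromosome axis
is an interference escape.  With 1 escape in 227 control nuclei versus
3 in 189 mutant nuclei, the Fisher exact test asks whether the escape
rate differs.
"""

from meioquant import double_focus_test

p = double_focus_test(n_double_a=1, n_total_a=227, n_double_b=3, n_total_b=189)
print(f"control: 1/227 double-focus nuclei; mutant: 3/189")
print(f"two-sided Fisher exact p = {p:.4f}")
# p is far above 0.05: no evidence that the mechanism limiting
# crossovers to one per chromosome pair differs between conditions.
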