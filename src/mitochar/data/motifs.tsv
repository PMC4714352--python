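# Control-region conserved blocks of sciaenid (croaker) mitogenomes.
# Mismatch budgets: 0 for the short low-complexity blocks, 2 for the
# 17-22 nt blocks; both are configuration, not biological fact.
Name	Consensus	MaxMismatch
ETAS_core	TACATAT	0
ETAS_palindrome	ATGTATA	0
CSB-F	ATGTAATAAGAACCGACCAT	2
CSB-E	AGGGACAAGTATTGTGGGGG	2
CSB-D	TATTCCTGGCATTTGGT	2
CSB-1	ATTTGGATATCAAGTGCATAAA	2
CSB-2	ACCCCCCCTACCCCCCC	0
CSB-3	AAACCCCCCGTAAA	0
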