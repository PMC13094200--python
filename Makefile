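.PHONY: demo test

demo:
	python -m neuromapopt.cli demo --seed 0 --n-patients 10 --out demo_out

test:
	python -m pytest -q tests/
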