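.PHONY: demo test acceptance clean

demo:
	rohsweep simulate -c examples/demo_config.yaml
	rohsweep run -c examples/demo_config.yaml

test:
	python -m pytest -q tests/

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json

clean:
	rm -rf demo_out results
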