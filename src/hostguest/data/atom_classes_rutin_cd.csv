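label,role,charge,kind
O1,guest,-0.57,acceptor
O2,guest,-0.452,acceptor
O3,guest,-0.419,acceptor
O4,guest,-0.32,acceptor
O5,guest,-0.1815,acceptor
O6,guest,-0.0685,acceptor
H1,guest,0.41,donorH
O7,host,-0.57,acceptor
O8,host,-0.32,acceptor
H2,host,0.41,donorH
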