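category,unit_price,price_year,source
gp,28.00,2009,standard
specialist,72.00,2009,standard
hospital,457.00,2009,standard
alternative,50.00,2009,tariff
mental,94.00,2009,standard
medication,25.00,2009,real_cost
aids,25.00,2009,lowest
other,33.00,2009,standard
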