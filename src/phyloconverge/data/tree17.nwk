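((sp03:38.352257050021926,(sp07:16.05297097806651,sp08:16.05297097806651):22.299286071955414):131.6477429499781,((sp01:60.690857298535164,sp02:60.690857298535164):90.08925219832855,((((sp06:16.280485874405837,(sp10:12.984887973077155,sp11:12.984887973077155):3.2955979013286814):3.898241851801305,((sp12:8.079163748777015,sp13:8.079163748777015):3.4134214945646426,(sp14:6.8226281734461995,sp15:6.8226281734461995):4.6699570698954584):8.686142482865485):17.210172384490235,(sp09:14.40458093424864,(sp16:0.3737724787033492,sp17:0.3737724787033492):14.03080845554529):22.98431917644874):39.03804208000645,(sp04:30.067726047934777,sp05:30.067726047934777):46.35921614276905):74.35316730615988):19.219890503136305):0.0;
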