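(Enoplida,(Trichinellida,(Plectida,(Spirurina,((Steinernematidae,((Alloionematidae,Strongyloididae),(Panagrolaimidae,(Cephalobomorpha,Tylenchomorpha))))Tylenchina,(Diplogastridae,(Strongylida,(Rhabditidae_other,Caenorhabditis)))Rhabditina)Rhabditina_Tylenchina)Rhabditida)))Nematoda;
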